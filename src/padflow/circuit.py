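"""Frequency-domain solver for the PCB's R-L-C analog network.

The physical board realises the arterial segment as two symmetric series
cells (R1-L1-C1 and R2-L2-C2) feeding a single parallel peripheral cell in
which a potentiometer (P1, alias R4, here labelled ``stenosis``) sits beside
the fixed peripheral resistor R3 and distal compliance C3.  Raising the
potentiometer's resistance emulates progressive lumen narrowing via the
Poiseuille scaling R ∝ r^-4, and raises the measured output voltage — the
electrical signature of pressure build-up across a stenosis.

The solver is standard complex modified nodal analysis (MNA): one admittance
row per non-ground node plus one current unknown for the ideal AC source.
Oscilloscope-style measurements (V_pp peak-to-peak, V_avg rectified cycle
mean) are derived from the solved output phasor, and a time-domain
synthesiser reproduces supply-rail clipping.
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Branch",
    "Source",
    "CircuitNetwork",
    "ACResponse",
    "WaveformTrace",
    "build_default_network",
    "mna_solve",
    "stenosis_to_resistance",
    "resistance_to_stenosis",
    "resistance_sweep",
    "synthesize_waveform",
    "DEFAULT_SWEEP_LEVELS",
]

#: The 40-step resistance grid: 2.5% to 100% of full scale in 2.5% steps.
DEFAULT_SWEEP_LEVELS = tuple(round(0.025 * i, 10) for i in range(1, 41))


@dataclass
class Branch:
    """One two-terminal element: kind in {R, L, C}, value in ohm/henry/farad."""

    kind: str
    value: float
    node_a: str
    node_b: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("R", "L", "C"):
            raise ValueError(f"branch kind must be R, L or C, got {self.kind!r}")
        if self.value <= 0:
            raise ValueError(f"branch {self.label!r}: value must be > 0, got {self.value!r}")

    def admittance(self, omega: float) -> complex:
        if self.kind == "R":
            return 1.0 / self.value
        if self.kind == "L":
            return 1.0 / (1j * omega * self.value)
        return 1j * omega * self.value  # C


@dataclass
class Source:
    """Ideal sinusoidal voltage source: amplitude (V), frequency (Hz), DC offset."""

    amplitude: float = 5.0
    frequency: float = 50.0
    offset: float = 0.0


@dataclass
class CircuitNetwork:
    """Netlist of R/L/C branches with designated ground, input and output nodes."""

    nodes: list[str]
    branches: list[Branch]
    source: Source = field(default_factory=Source)
    ground: str = "gnd"
    input_node: str = "in"
    output_node: str = "out"
    variable_label: str = "stenosis"
    variable_full_scale: float = 1000.0

    def __post_init__(self) -> None:
        for required in (self.ground, self.input_node, self.output_node):
            if required not in self.nodes:
                raise ValueError(f"node {required!r} missing from node list")
        self._check_connected()

    def _check_connected(self) -> None:
        adjacency: dict[str, set[str]] = {n: set() for n in self.nodes}
        for b in self.branches:
            adjacency[b.node_a].add(b.node_b)
            adjacency[b.node_b].add(b.node_a)
        seen = {self.ground}
        stack = [self.ground]
        while stack:
            for nxt in adjacency[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        # the source ties input to ground, so input is always reachable
        seen.add(self.input_node)
        floating = set(self.nodes) - seen
        if floating:
            raise ValueError(f"disconnected node(s): {sorted(floating)}")

    @property
    def variable_branch(self) -> Branch:
        for b in self.branches:
            if b.label == self.variable_label:
                return b
        raise KeyError(f"no branch labelled {self.variable_label!r}")

    def with_variable_resistance(self, value: float) -> "CircuitNetwork":
        """Copy of the network with the stenosis resistor set to ``value`` ohms."""
        if value <= 0:
            raise ValueError(f"resistance must be > 0, got {value!r}")
        branches = [
            Branch(b.kind, value if b.label == self.variable_label else b.value, b.node_a, b.node_b, b.label)
            for b in self.branches
        ]
        return CircuitNetwork(
            nodes=list(self.nodes),
            branches=branches,
            source=Source(**asdict(self.source)),
            ground=self.ground,
            input_node=self.input_node,
            output_node=self.output_node,
            variable_label=self.variable_label,
            variable_full_scale=self.variable_full_scale,
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "branches": [asdict(b) for b in self.branches],
            "source": asdict(self.source),
            "ground": self.ground,
            "input_node": self.input_node,
            "output_node": self.output_node,
            "variable_label": self.variable_label,
            "variable_full_scale": self.variable_full_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitNetwork":
        return cls(
            nodes=list(d["nodes"]),
            branches=[Branch(**b) for b in d["branches"]],
            source=Source(**d.get("source", {})),
            ground=d.get("ground", "gnd"),
            input_node=d.get("input_node", "in"),
            output_node=d.get("output_node", "out"),
            variable_label=d.get("variable_label", "stenosis"),
            variable_full_scale=d.get("variable_full_scale", 1000.0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CircuitNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ACResponse:
    """Solved node phasors and oscilloscope-style measurements.

    ``v_pp = 2|u_out|`` and ``v_avg = (2/pi)|u_out|`` (rectified mean) hold
    for an unclipped sinusoid; :func:`synthesize_waveform` recomputes both
    from a clipped trace when rails matter.
    """

    node_phasors: dict[str, complex]
    u_in: float
    u_out: float
    v_pp: float
    v_avg: float
    frequency: float

    @property
    def output_phase(self) -> float:
        return cmath.phase(self.node_phasors["__out__"])


def build_default_network() -> CircuitNetwork:
    """Canonical board netlist with the printed component values.

    R1 = 71.6, R2 = 0.8, R3 = 83.4 ohm; C1 = C2 = C3 = 490 nF;
    L1 = L2 = 0.000209 mH; P1 full scale 1 kohm; 0-5 V AC source at 50 Hz.
    Topology: in -R1- L1 - A (C1 to gnd) -R2- L2 - out (C2 to gnd) with the
    parallel peripheral cell {R3 || P1 || C3} from out to ground.
    """
    L_H = 0.000209e-3  # printed as 0.000209 mH
    branches = [
        Branch("R", 71.6, "in", "n1", "R1"),
        Branch("L", L_H, "n1", "A", "L1"),
        Branch("C", 490e-9, "A", "gnd", "C1"),
        Branch("R", 0.8, "A", "n2", "R2"),
        Branch("L", L_H, "n2", "out", "L2"),
        Branch("C", 490e-9, "out", "gnd", "C2"),
        Branch("R", 83.4, "out", "gnd", "R3"),
        Branch("C", 490e-9, "out", "gnd", "C3"),
        Branch("R", 25.0, "out", "gnd", "stenosis"),  # P1/R4 at first sweep level
    ]
    return CircuitNetwork(
        nodes=["gnd", "in", "n1", "A", "n2", "out"],
        branches=branches,
        source=Source(amplitude=5.0, frequency=50.0, offset=0.0),
        variable_full_scale=1000.0,
    )


def mna_solve(net: CircuitNetwork, f: float | None = None) -> ACResponse:
    """Solve the network at frequency ``f`` (defaults to the source frequency).

    Assembles the complex node-admittance system with one extra current
    unknown for the ideal source and solves it directly.  A singular system
    raises ``ValueError`` naming the floating node when one can be identified.
    """
    if f is None:
        f = net.source.frequency
    if f <= 0:
        raise ValueError(f"frequency must be > 0, got {f!r}")
    omega = 2.0 * math.pi * f
    unknowns = [n for n in net.nodes if n != net.ground]
    index = {n: i for i, n in enumerate(unknowns)}
    n = len(unknowns)
    # last row/column: source current through the ideal source at input_node
    A = np.zeros((n + 1, n + 1), dtype=complex)
    b = np.zeros(n + 1, dtype=complex)
    for br in net.branches:
        y = br.admittance(omega)
        ia = index.get(br.node_a)
        ib = index.get(br.node_b)
        if ia is not None:
            A[ia, ia] += y
        if ib is not None:
            A[ib, ib] += y
        if ia is not None and ib is not None:
            A[ia, ib] -= y
            A[ib, ia] -= y
    k = index[net.input_node]
    A[k, n] = 1.0
    A[n, k] = 1.0
    b[n] = net.source.amplitude
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        diag = np.abs(np.diag(A)[:n])
        if (diag == 0).any():
            bad = unknowns[int(np.argmin(diag))]
            raise ValueError(f"singular network: node {bad!r} has no connection") from exc
        raise ValueError("singular network: admittance system not solvable") from exc
    phasors = {net.ground: 0.0 + 0.0j}
    for name, i in index.items():
        phasors[name] = complex(x[i])
    out = phasors[net.output_node]
    phasors["__out__"] = out
    amp_out = abs(out)
    return ACResponse(
        node_phasors=phasors,
        u_in=abs(phasors[net.input_node]),
        u_out=amp_out,
        v_pp=2.0 * amp_out,
        v_avg=(2.0 / math.pi) * amp_out,
        frequency=f,
    )


def stenosis_to_resistance(sigma: float, R_base: float) -> float:
    """Lesion resistance R_base*(1 - sigma)^-4 from the r^-4 Poiseuille law."""
    if not (0.0 <= sigma < 1.0):
        raise ValueError(f"sigma must lie in [0, 1), got {sigma!r}")
    if R_base <= 0:
        raise ValueError(f"R_base must be > 0, got {R_base!r}")
    return R_base * (1.0 - sigma) ** -4


def resistance_to_stenosis(Rv: float, R_base: float) -> float:
    """Exact inverse of :func:`stenosis_to_resistance`."""
    if R_base <= 0:
        raise ValueError(f"R_base must be > 0, got {R_base!r}")
    if Rv < R_base:
        raise ValueError(f"Rv must be >= R_base ({Rv!r} < {R_base!r})")
    return 1.0 - (R_base / Rv) ** 0.25


def resistance_sweep(
    net: CircuitNetwork | None = None,
    levels: Sequence[float] = DEFAULT_SWEEP_LEVELS,
    f: float | None = None,
) -> pd.DataFrame:
    """Sweep the variable resistor over fractional levels of its full scale.

    Returns one row per level with U_in, U_out, V_pp (mV), V_avg (mV) at the
    source frequency; per-row solver failures are flagged, not raised.
    """
    if net is None:
        net = build_default_network()
    rows = []
    for i, level in enumerate(levels, start=1):
        row: dict = {
            "test": i,
            "level": float(level),
            "R_ohm": float(level) * net.variable_full_scale,
            "error": "",
        }
        try:
            if level <= 0:
                raise ValueError(f"sweep level must be > 0, got {level!r}")
            solved = mna_solve(net.with_variable_resistance(row["R_ohm"]), f)
        except ValueError as exc:
            row["error"] = str(exc)
            rows.append(row)
            continue
        row.update(
            Uin_V=solved.u_in,
            Uout_V=solved.u_out,
            Vpp_mV=solved.v_pp * 1e3,
            Vavg_mV=solved.v_avg * 1e3,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WaveformTrace:
    """Sampled (possibly clipped) output trace with recomputed measurements."""

    t: np.ndarray
    u: np.ndarray
    v_pp: float
    v_avg: float
    clipped: bool


def synthesize_waveform(
    resp: ACResponse,
    rails: float = 5.0,
    n_cycles: int = 5,
    samples_per_cycle: int = 1000,
) -> WaveformTrace:
    """Time-domain sinusoid at the solved output amplitude/phase, hard-clipped.

    The trace is clipped at ±``rails`` volts (the supply range); V_pp is
    max - min and V_avg the rectified mean, both over the final full cycle —
    matching how an oscilloscope reports a clipped signal.
    """
    if rails <= 0:
        raise ValueError(f"rails must be > 0, got {rails!r}")
    amp = resp.u_out
    phase = resp.output_phase
    T = 1.0 / resp.frequency
    t = np.arange(n_cycles * samples_per_cycle) * (T / samples_per_cycle)
    u = amp * np.sin(2.0 * math.pi * resp.frequency * t + phase)
    clipped = bool(amp > rails)
    u = np.clip(u, -rails, rails)
    last = u[-samples_per_cycle:]
    return WaveformTrace(
        t=t,
        u=u,
        v_pp=float(last.max() - last.min()),
        v_avg=float(np.abs(last).mean()),
        clipped=clipped,
    )
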