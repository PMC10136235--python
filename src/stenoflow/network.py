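"""Branching arterial tree: wall law, Windkessel outlets, afterload algebra.

Vessel distensibility follows the Langewouters arctangent pressure-area
relation

    A(P) = Amax * (1/2 + arctan((P - P0)/P1) / pi)

whose compliance dA/dP = Amax / (pi*P1*(1 + ((P-P0)/P1)^2)) peaks at the
inflection pressure P0 and whose width pressure P1 sets the stiffness.
Geometry files store the cross-sectional area at a reference pressure
(95 mmHg by default); Amax is recovered from it.  Wall-law parameters
are linearly interpolated along each segment.

Each terminal segment ends in a three-element Windkessel (proximal
resistance R1, distal resistance R2, compliance Ct).  The aggregate
afterload of the tree is summarized by the total vascular resistance
TVR (parallel combination of the terminal R1+R2) and the total arterial
compliance TAC (volume-integrated vessel compliance at the operating
pressure plus the sum of terminal compliances); both can be rescaled to
prescribed targets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .units import MMHG

#: reference pressure (mmHg) at which geometry areas are specified
P_REF = 95.0

#: accepted target ranges for afterload rescaling (mmHg*s/mL, mL/mmHg)
TVR_BOUNDS = (0.3, 3.0)
TAC_BOUNDS = (0.2, 4.0)

GEOMETRY_COLUMNS = [
    "id", "parent_id", "length_cm", "area_prox_cm2", "area_dist_cm2",
    "p0_mmhg", "p1_mmhg", "visc_coeff", "terminal_r1", "terminal_r2",
    "terminal_ct",
]


def langewouters_area(p, amax, p0, p1):
    """Cross-sectional area A(P), cm^2 (pressures in mmHg)."""
    return amax * (0.5 + np.arctan((np.asarray(p, dtype=float) - p0) / p1) / np.pi)


def langewouters_compliance(p, amax, p0, p1):
    """Local compliance dA/dP, cm^2/mmHg; maximal at P = P0."""
    xi = (np.asarray(p, dtype=float) - p0) / p1
    return amax / (np.pi * p1 * (1.0 + xi * xi))


def langewouters_pressure(a, amax, p0, p1):
    """Inverse wall law P(A), mmHg (A strictly inside (0, Amax))."""
    ratio = np.asarray(a, dtype=float) / amax
    return p0 + p1 * np.tan(np.pi * (ratio - 0.5))


def wave_speed(p, amax, p0, p1, rho=1.06):
    """Local pulse-wave speed c = sqrt(A/(rho * dA/dP)), cm/s."""
    a = langewouters_area(p, amax, p0, p1)
    dadp = langewouters_compliance(p, amax, p0, p1) / MMHG  # cm^2 per dyn/cm^2
    return np.sqrt(a / (rho * dadp))


def amax_from_reference(a_ref, p0, p1, p_ref=P_REF):
    """Asymptotic area giving A(p_ref) = a_ref."""
    return a_ref / (0.5 + np.arctan((p_ref - p0) / p1) / np.pi)


@dataclass
class WindkesselTerminal:
    """Three-element Windkessel outlet (clinical units)."""

    r1: float  # mmHg*s/mL
    r2: float  # mmHg*s/mL
    ct: float  # mL/mmHg
    pc: float = 80.0  # stored compartment pressure, mmHg

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0 or self.ct <= 0:
            raise ValueError("Windkessel R1, R2, Ct must all be positive")


def windkessel_step(terminal: WindkesselTerminal, q_in: float, dt: float) -> float:
    """Advance the Windkessel one step; returns the outlet pressure, mmHg.

    Compartment ODE dPc/dt = (Q - Pc/R2)/Ct advanced implicitly; outlet
    pressure P = Pc + Q*R1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    terminal.pc = (terminal.pc + dt * q_in / terminal.ct) / (1.0 + dt / (terminal.r2 * terminal.ct))
    return terminal.pc + q_in * terminal.r1


@dataclass
class ArterialSegment:
    """One 1D segment; areas are taken at the reference pressure P_REF."""

    id: int
    parent_id: int | None
    length: float  # cm
    area_prox: float  # cm^2 at P_REF
    area_dist: float  # cm^2 at P_REF
    p0: float  # mmHg
    p1: float  # mmHg
    visc_coeff: float = 0.0  # Kelvin-Voigt, mmHg*s per unit fractional area rate
    terminal: WindkesselTerminal | None = None
    children: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be positive")
        if self.area_prox <= 0 or self.area_dist <= 0:
            raise ValueError(f"segment {self.id}: areas must be positive")
        if self.p1 <= 0:
            raise ValueError(f"segment {self.id}: P1 must be positive")

    def compliance_integral(self, p: float) -> float:
        """Volume compliance of the segment at pressure p: int dA/dP dx, mL/mmHg."""
        x = np.linspace(0.0, 1.0, 21)
        a_ref = self.area_prox + (self.area_dist - self.area_prox) * x
        amax = amax_from_reference(a_ref, self.p0, self.p1)
        dadp = langewouters_compliance(p, amax, self.p0, self.p1)
        return float(np.trapezoid(dadp, x) * self.length)


class ArterialTree:
    """Validated container for a branching arterial geometry."""

    def __init__(self, segments: list[ArterialSegment]):
        self.segments = {s.id: s for s in segments}
        if len(self.segments) != len(segments):
            raise ValueError("duplicate segment ids")
        self._validate()

    def _validate(self) -> None:
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for s in self.segments.values():
            s.children = []
        for s in self.segments.values():
            if s.parent_id is not None:
                if s.parent_id not in self.segments:
                    raise ValueError(f"segment {s.id}: unknown parent {s.parent_id}")
                self.segments[s.parent_id].children.append(s.id)
        # connectivity + acyclicity by traversal from the root
        seen: set[int] = set()
        stack = [self.root.id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError(f"cycle detected at segment {sid}")
            seen.add(sid)
            stack.extend(self.segments[sid].children)
        if seen != set(self.segments):
            raise ValueError("tree is not connected: unreachable segments "
                             f"{sorted(set(self.segments) - seen)}")
        for s in self.segments.values():
            if not s.children and s.terminal is None:
                raise ValueError(f"leaf segment {s.id} lacks a Windkessel terminal")
            if s.children and s.terminal is not None:
                raise ValueError(f"internal segment {s.id} carries a terminal")
            if len(s.children) > 3:
                raise ValueError(f"segment {s.id}: more than 3 children unsupported")

    @property
    def terminals(self) -> dict[int, WindkesselTerminal]:
        return {s.id: s.terminal for s in self.segments.values() if s.terminal is not None}

    def n_segments(self) -> int:
        return len(self.segments)

    def copy(self) -> "ArterialTree":
        segs = []
        for s in self.segments.values():
            term = replace(s.terminal) if s.terminal is not None else None
            segs.append(replace(s, terminal=term, children=[]))
        return ArterialTree(segs)

    # ------------------------------------------------------------------
    # afterload algebra
    # ------------------------------------------------------------------
    def aggregate_afterload(self, p_ref: float = P_REF) -> tuple[float, float]:
        """(TVR, TAC): parallel terminal resistance and total compliance.

        TVR = [sum_k 1/(R1_k + R2_k)]^-1 (mmHg*s/mL); TAC = vessel
        compliance integrated at ``p_ref`` plus the terminal compliances
        (mL/mmHg).
        """
        g = sum(1.0 / (t.r1 + t.r2) for t in self.terminals.values())
        tvr = 1.0 / g
        tac = sum(s.compliance_integral(p_ref) for s in self.segments.values())
        tac += sum(t.ct for t in self.terminals.values())
        return tvr, tac

    def scale_afterload(self, tvr_target: float, tac_target: float,
                        p_ref: float = P_REF) -> "ArterialTree":
        """Return a copy rescaled to the requested aggregate afterload.

        All terminal resistances share one exact factor.  Compliances are
        scaled through the asymptotic areas (vessel calibre): scaling
        Amax (equivalently the reference areas) multiplies the wall
        compliance dA/dP by the same factor at *every* pressure and
        leaves pulse-wave speeds unchanged, so a nominally compliant tree
        stays compliant at systolic pressures too.  Terminal compliances
        share the same factor, making aggregate TAC exactly linear in it.
        """
        if not (TVR_BOUNDS[0] <= tvr_target <= TVR_BOUNDS[1]):
            raise ValueError(f"TVR target {tvr_target} outside bounds {TVR_BOUNDS}")
        if not (TAC_BOUNDS[0] <= tac_target <= TAC_BOUNDS[1]):
            raise ValueError(f"TAC target {tac_target} outside bounds {TAC_BOUNDS}")
        tree = self.copy()
        tvr0, tac0 = tree.aggregate_afterload(p_ref)
        fr = tvr_target / tvr0
        for t in tree.terminals.values():
            t.r1 *= fr
            t.r2 *= fr
        s = tac_target / tac0
        for seg in tree.segments.values():
            seg.area_prox *= s
            seg.area_dist *= s
            if seg.terminal is not None:
                seg.terminal.ct *= s
        return tree

    # ------------------------------------------------------------------
    # geometry file I/O
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments.values():
            t = s.terminal
            rows.append({
                "id": s.id,
                "parent_id": s.parent_id if s.parent_id is not None else np.nan,
                "length_cm": s.length,
                "area_prox_cm2": s.area_prox,
                "area_dist_cm2": s.area_dist,
                "p0_mmhg": s.p0,
                "p1_mmhg": s.p1,
                "visc_coeff": s.visc_coeff,
                "terminal_r1": t.r1 if t else np.nan,
                "terminal_r2": t.r2 if t else np.nan,
                "terminal_ct": t.ct if t else np.nan,
            })
        return pd.DataFrame(rows, columns=GEOMETRY_COLUMNS).sort_values("id").reset_index(drop=True)

    def save(self, path, header_comment: str | None = None) -> None:
        buf = io.StringIO()
        if header_comment:
            for line in header_comment.splitlines():
                buf.write(f"# {line}\n")
        self.to_frame().to_csv(buf, index=False, float_format="%.8g")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArterialTree":
        missing = set(GEOMETRY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"geometry file missing columns: {sorted(missing)}")
        segs = []
        for _, r in df.iterrows():
            term = None
            if np.isfinite(r["terminal_r1"]):
                term = WindkesselTerminal(r1=float(r["terminal_r1"]),
                                          r2=float(r["terminal_r2"]),
                                          ct=float(r["terminal_ct"]))
            parent = None if pd.isna(r["parent_id"]) else int(r["parent_id"])
            segs.append(ArterialSegment(
                id=int(r["id"]), parent_id=parent, length=float(r["length_cm"]),
                area_prox=float(r["area_prox_cm2"]), area_dist=float(r["area_dist_cm2"]),
                p0=float(r["p0_mmhg"]), p1=float(r["p1_mmhg"]),
                visc_coeff=float(r["visc_coeff"]) if np.isfinite(r["visc_coeff"]) else 0.0,
                terminal=term))
        return cls(segs)

    @classmethod
    def load(cls, path) -> "ArterialTree":
        df = pd.read_csv(path, comment="#")
        return cls.from_frame(df)


def load_geometry(path) -> ArterialTree:
    """Load and validate a geometry CSV (see GEOMETRY_COLUMNS for schema)."""
    return ArterialTree.load(path)


def aggregate_afterload(tree: ArterialTree, p_ref: float = P_REF) -> tuple[float, float]:
    return tree.aggregate_afterload(p_ref)


def scale_afterload(tree: ArterialTree, tvr_target: float, tac_target: float,
                    p_ref: float = P_REF) -> ArterialTree:
    return tree.scale_afterload(tvr_target, tac_target, p_ref)
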