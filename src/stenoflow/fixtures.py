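"""Synthetic arterial geometries and patient fixtures.

The published whole-body geometries behind 1D arterial models are not
redistributable, so this module generates physiologically plausible
stand-ins: an aortic trunk with distal taper, the major branch vessels,
wave speeds rising from roughly 4 m/s at the root to 9 m/s in the limbs,
and terminal Windkessels whose aggregate resistance and compliance land
inside the physiological ranges used for the sweeps.  The default
packaged tree has 24 segments; a 103-segment refinement with the same
topology is shipped for workloads that expect a dense tree.  All trees
are explicitly synthetic (non-anatomical) and labelled as such in their
file headers.

Patient fixtures bundle the cardiac/valve inputs of the two worked
examples: the catheterized severe-stenosis patient (PV-loop study) and
the rest/stress dobutamine echo pair.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .network import (P_REF, ArterialSegment, ArterialTree, WindkesselTerminal,
                      amax_from_reference, wave_speed)
from .units import MMHG, RHO_BLOOD

SYNTHETIC_HEADER = (
    "SYNTHETIC arterial tree generated by stenoflow.fixtures - "
    "plausible but NON-ANATOMICAL geometry, not derived from any "
    "published segment table."
)


@dataclass
class BranchSpec:
    """One branch vessel: where it takes off and its properties."""

    name: str
    takeoff: int  # index of the aortic segment it branches from (junction at its end)
    length: float  # cm
    area_prox: float  # cm^2 at reference pressure
    area_dist: float
    c_target: float  # pulse-wave speed target at reference pressure, cm/s
    weight: float | None = None  # fraction of cardiac output (terminal) or None
    parent_branch: str | None = None  # chains off another branch instead of the aorta


@dataclass
class TreeBlueprint:
    """Parameters of the synthetic tree generator.

    ``aortic_*`` arrays describe the trunk; ``branches`` the side
    vessels; ``ct_total`` the summed terminal compliance (mL/mmHg) and
    ``tvr`` the aggregate resistance (mmHg*s/mL) distributed over the
    terminals by their flow ``weight``.  ``jitter`` applies a seeded
    relative perturbation to lengths and areas.
    """

    aortic_lengths: tuple = (4.0, 3.0, 3.0, 5.0, 5.0, 5.0, 5.0, 5.0)
    aortic_areas: tuple = (5.3, 5.0, 4.8, 4.5, 4.3, 3.8, 3.6, 3.0, 2.8,
                           2.4, 2.2, 1.8, 1.7, 1.4, 1.3, 1.1)  # prox/dist pairs
    aortic_c: tuple = (420.0, 445.0, 470.0, 495.0, 520.0, 545.0, 570.0, 600.0)
    p0: float = 70.0
    branches: list = field(default_factory=lambda: _default_branches())
    tvr: float = 1.0
    ct_total: float = 0.55
    r1_fraction: float = 0.2
    jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        root_area = self.aortic_areas[0]
        if not (3.0 <= root_area <= 7.0):
            raise ValueError(f"root area {root_area} cm^2 outside ascending-aorta "
                             "scale [3, 7]")
        if len(self.aortic_areas) != 2 * len(self.aortic_lengths):
            raise ValueError("aortic_areas must hold prox/dist pairs per segment")
        w = [b.weight for b in self.branches if b.weight is not None]
        if not w or abs(sum(w) - 1.0) > 0.25:
            raise ValueError("terminal flow weights must roughly sum to 1")


def _default_branches() -> list:
    return [
        BranchSpec("carotid_r", 0, 15.0, 0.50, 0.40, 650.0, 0.080),
        BranchSpec("subclavian_r", 0, 5.0, 0.55, 0.45, 650.0, None),
        BranchSpec("vertebral_r", -1, 14.0, 0.13, 0.10, 800.0, 0.030, "subclavian_r"),
        BranchSpec("brachial_r", -1, 25.0, 0.40, 0.25, 800.0, 0.060, "subclavian_r"),
        BranchSpec("carotid_l", 1, 15.0, 0.50, 0.40, 650.0, 0.080),
        BranchSpec("subclavian_l", 1, 5.0, 0.55, 0.45, 650.0, None),
        BranchSpec("vertebral_l", -1, 14.0, 0.13, 0.10, 800.0, 0.030, "subclavian_l"),
        BranchSpec("brachial_l", -1, 25.0, 0.40, 0.25, 800.0, 0.060, "subclavian_l"),
        BranchSpec("celiac", 3, 3.0, 0.60, 0.50, 700.0, 0.180),
        BranchSpec("mesenteric", 4, 5.0, 0.45, 0.40, 700.0, 0.120),
        BranchSpec("renal_r", 5, 3.0, 0.30, 0.25, 750.0, 0.100),
        BranchSpec("renal_l", 5, 3.0, 0.30, 0.25, 750.0, 0.100),
        BranchSpec("iliac_r", 7, 8.0, 0.45, 0.35, 800.0, None),
        BranchSpec("femoral_r", -1, 25.0, 0.32, 0.20, 900.0, 0.085, "iliac_r"),
        BranchSpec("iliac_l", 7, 8.0, 0.45, 0.35, 800.0, None),
        BranchSpec("femoral_l", -1, 25.0, 0.32, 0.20, 900.0, 0.085, "iliac_l"),
    ]


def _p1_for_wave_speed(c_target: float, p0: float, p_ref: float = P_REF,
                       rho: float = RHO_BLOOD) -> float:
    """Width pressure P1 (mmHg) giving wave speed c_target at p_ref.

    With A/Amax = 1/2 + arctan(xi)/pi and xi = (p_ref - p0)/P1,
    c^2 = (A/Amax) * pi * P1 * (1 + xi^2) / rho (P1 in dyn/cm^2);
    solved by fixed-point iteration on xi.
    """
    p1 = 50.0
    for _ in range(60):
        xi = (p_ref - p0) / p1
        ratio = 0.5 + np.arctan(xi) / np.pi
        p1_new = c_target**2 * rho / (ratio * np.pi * MMHG * (1.0 + xi * xi))
        if abs(p1_new - p1) < 1e-10 * p1:
            p1 = p1_new
            break
        p1 = 0.5 * (p1 + p1_new)
    return float(p1)


def generate_tree(blueprint: TreeBlueprint | None = None, seed: int | None = None) -> ArterialTree:
    """Build a synthetic arterial tree from a blueprint (deterministic per seed)."""
    bp = blueprint if blueprint is not None else TreeBlueprint()
    if seed is not None:
        bp = copy.deepcopy(bp)
        bp.seed = seed
    rng = np.random.default_rng(bp.seed)
    n_aorta = len(bp.aortic_lengths)

    def jit() -> float:
        return 1.0 + bp.jitter * float(rng.uniform(-1.0, 1.0))

    segs: list[ArterialSegment] = []
    name_to_id: dict[str, int] = {}
    for i in range(n_aorta):
        p1 = _p1_for_wave_speed(bp.aortic_c[i], bp.p0)
        sc = jit()
        segs.append(ArterialSegment(
            id=i, parent_id=None if i == 0 else i - 1,
            length=bp.aortic_lengths[i] * jit(),
            area_prox=bp.aortic_areas[2 * i] * sc,
            area_dist=bp.aortic_areas[2 * i + 1] * sc,
            p0=bp.p0, p1=p1))
        name_to_id[f"aorta_{i}"] = i

    weights = {}
    next_id = n_aorta
    for b in bp.branches:
        if b.parent_branch is not None:
            parent = name_to_id[b.parent_branch]
        else:
            parent = b.takeoff
        p1 = _p1_for_wave_speed(b.c_target, bp.p0)
        sc = jit()
        segs.append(ArterialSegment(
            id=next_id, parent_id=parent, length=b.length * jit(),
            area_prox=b.area_prox * sc, area_dist=b.area_dist * sc,
            p0=bp.p0, p1=p1))
        name_to_id[b.name] = next_id
        if b.weight is not None:
            weights[next_id] = b.weight
        next_id += 1

    wsum = sum(weights.values())
    for sid, w in weights.items():
        s = segs[sid]
        wn = w / wsum
        r_tot = bp.tvr / wn
        amx = amax_from_reference(s.area_dist, s.p0, s.p1)
        z_c = RHO_BLOOD * wave_speed(P_REF, amx, s.p0, s.p1) / s.area_dist / MMHG
        r1 = min(float(z_c), bp.r1_fraction * r_tot)
        s.terminal = WindkesselTerminal(r1=r1, r2=r_tot - r1, ct=bp.ct_total * wn)

    tree = ArterialTree(segs)
    _validate_blueprint_invariants(tree)
    return tree


def _validate_blueprint_invariants(tree: ArterialTree) -> None:
    root_area = tree.root.area_prox
    if not (3.0 <= root_area <= 7.0):
        raise ValueError(f"generated root area {root_area:.2f} cm^2 outside [3, 7]")
    for s in tree.segments.values():
        if s.children:
            ratio = sum(tree.segments[c].area_prox for c in s.children) / s.area_dist
            if not (0.65 <= ratio <= 1.40):
                raise ValueError(
                    f"junction at segment {s.id}: summed daughter/parent area "
                    f"ratio {ratio:.2f} outside [0.65, 1.40]")
            c_par = wave_speed(P_REF, amax_from_reference(s.area_dist, s.p0, s.p1),
                               s.p0, s.p1)
            for c in s.children:
                ch = tree.segments[c]
                c_ch = wave_speed(P_REF, amax_from_reference(ch.area_prox, ch.p0, ch.p1),
                                  ch.p0, ch.p1)
                if c_ch < 0.95 * c_par:
                    raise ValueError(
                        f"wave speed drops from segment {s.id} to child {c}: "
                        f"{c_par:.0f} -> {c_ch:.0f} cm/s")


def subdivide_tree(tree: ArterialTree, n_total: int) -> ArterialTree:
    """Split segments into shorter pieces until the tree has n_total segments.

    Extra cuts are distributed to the longest remaining pieces, so the
    topology (junctions, terminals, aggregate afterload) is preserved
    while the segment count rises.
    """
    n_extra = n_total - tree.n_segments()
    if n_extra < 0:
        raise ValueError("n_total below current segment count")
    parts = {sid: 1 for sid in tree.segments}
    for _ in range(n_extra):
        sid = max(parts, key=lambda k: tree.segments[k].length / parts[k])
        parts[sid] += 1

    segs: list[ArterialSegment] = []
    new_first: dict[int, int] = {}
    new_last: dict[int, int] = {}
    nid = 0
    for sid in tree.segments:  # insertion order: root first
        s = tree.segments[sid]
        k = parts[sid]
        new_first[sid] = nid
        for j in range(k):
            f0, f1 = j / k, (j + 1) / k
            a0 = s.area_prox + (s.area_dist - s.area_prox) * f0
            a1 = s.area_prox + (s.area_dist - s.area_prox) * f1
            term = None
            if j == k - 1 and s.terminal is not None:
                t = s.terminal
                term = WindkesselTerminal(r1=t.r1, r2=t.r2, ct=t.ct)
            segs.append(ArterialSegment(
                id=nid, parent_id=nid - 1 if j > 0 else -1,  # parent fixed below
                length=s.length / k, area_prox=a0, area_dist=a1,
                p0=s.p0, p1=s.p1, visc_coeff=s.visc_coeff, terminal=term))
            nid += 1
        new_last[sid] = nid - 1
    # rewire parents across original topology
    for sid in tree.segments:
        s = tree.segments[sid]
        first = new_first[sid]
        if s.parent_id is None:
            segs[first].parent_id = None
        else:
            segs[first].parent_id = new_last[s.parent_id]
    return ArterialTree(segs)


def tree24(seed: int = 0) -> ArterialTree:
    """The default 24-segment synthetic tree."""
    return generate_tree(TreeBlueprint(seed=seed))


def tree103(seed: int = 0) -> ArterialTree:
    """A 103-segment refinement of the default synthetic tree."""
    return subdivide_tree(tree24(seed=seed), 103)


def packaged_tree(name: str) -> ArterialTree:
    """Load a tree shipped inside the distribution ('tree24' or 'tree103')."""
    ref = resources.files("stenoflow") / "data" / f"{name}.csv"
    if not ref.is_file():
        raise KeyError(f"no packaged geometry named {name!r}")
    with resources.as_file(ref) as path:
        return ArterialTree.load(path)


def patient_fixture(name: str):
    """Pre-configured worked-example cases.

    ``dekker_av_stenosis``: catheterized severe-stenosis patient
    (Ees 3.3, Eed 0.1 mmHg/mL, Vd 39.3 mL, LVEDP 11 mmHg, AVA 0.6 cm^2).
    ``dobutamine_rest`` / ``dobutamine_stress``: AVA 0.88 cm^2 with
    stroke-volume targets 67 and 87 mL.
    """
    from .cardiac import CardiacParams
    from .simulator import SimulationConfig
    from .valve import ValveParams

    if name == "dekker_av_stenosis":
        return SimulationConfig(
            cardiac=CardiacParams(ees=3.3, eed=0.1, lvedp=11.0, vd=39.3),
            valve=ValveParams(ames=0.6),
            geometry="tree24")
    if name in ("dobutamine_rest", "dobutamine_stress"):
        sv = 67.0 if name == "dobutamine_rest" else 87.0
        return SimulationConfig(
            cardiac=CardiacParams(ees=2.0, eed=0.1, lvedp=11.0, vd=39.3),
            valve=ValveParams(ames=0.88),
            geometry="tree24", sv_target=sv)
    raise KeyError(f"unknown patient fixture {name!r}")
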