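"""Synthetic vascular phantoms and synthetic cohorts with known ground truth.

Phantoms are unions of capsules (line segments with a radius) rasterized on a
voxel grid: a voxel is vessel iff its centre lies within the edge radius of
any edge segment.  Ground truth (endpoint, bifurcation and crossing counts,
exact centreline length, component count) is always derived from the
node/edge graph, never from the rasterized volume.

The "clean tree" family used for exact topology-recovery experiments places
nodes on integer lattice coordinates and draws each bifurcation's direction
triple from a frozen catalogue of junction geometries that are known to thin
to exactly one 3-neighbour voxel (see ``_junction_catalog``).  Trees outside
this family still rasterize fine but may spread a junction over adjacent
voxels after thinning, as real Doppler data does.

Synthetic cohorts emulate a longitudinal first-trimester study: subjects
scanned at 7, 9 and 11 weeks gestational age with partial attendance, a
quadratic-in-GA median trajectory per characteristic, a subject-level random
intercept, multiplicative log-normal noise, and a binary placenta-related
complication stratum with multiplicative effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._junction_catalog import CLEAN_JUNCTION_TRIPLES
from .io_volumes import DopplerVolume, RegionMask
from .morphology import density_ratios, MorphCharacteristics

#: Intensity given to vessel voxels; comfortably above the default threshold.
DEFAULT_VESSEL_INTENSITY = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric specification of a tubular phantom.

    ``nodes`` are float (z, y, x) voxel coordinates; ``edges`` are
    (node_index, node_index) pairs with per-edge ``radii`` in voxels.
    Artefact counts request supra-threshold stripe planes, solid blobs and
    isolated voxels to be overlaid by :func:`add_artifacts`.
    """

    shape: tuple[int, int, int]
    nodes: tuple[tuple[float, float, float], ...]
    edges: tuple[tuple[int, int], ...]
    radii: tuple[float, ...]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    vessel_intensity: int = DEFAULT_VESSEL_INTENSITY
    background_intensity: int = 0
    n_stripes: int = 0
    n_blobs: int = 0
    n_isolated: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.radii) != len(self.edges):
            raise ValueError("one radius per edge required")
        if any(r < 1 for r in self.radii):
            raise ValueError("edge radii must be >= 1 voxel")
        rmax = max(self.radii, default=1.0)
        arr = np.asarray(self.nodes, float)
        if arr.size:
            lo = arr.min(axis=0)
            hi = np.asarray(self.shape) - 1 - arr.max(axis=0)
            if lo.min() < rmax or hi.min() < rmax:
                raise ValueError(
                    "nodes must keep a margin of at least the maximum radius "
                    "from the grid border")

    def degrees(self) -> dict[int, int]:
        deg: dict[int, int] = {}
        for i, j in self.edges:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        return deg


@dataclass(frozen=True)
class GroundTruth:
    """Graph-derived truth for a phantom: node-class counts and length."""

    n_end: int
    n_bif: int
    n_cross: int
    total_length_mm: float
    n_components: int


def _graph_truth(spec: PhantomSpec) -> GroundTruth:
    deg = spec.degrees()
    n_end = sum(1 for v in deg.values() if v == 1)
    n_bif = sum(1 for v in deg.values() if v == 3)
    n_cross = sum(1 for v in deg.values() if v == 4)
    sp = np.asarray(spec.spacing)
    nodes = np.asarray(spec.nodes, float)
    length = sum(
        float(np.linalg.norm((nodes[j] - nodes[i]) * sp)) for i, j in spec.edges
    )
    # union-find over nodes touched by edges
    parent = {}

    def find(a):
        while parent.get(a, a) != a:
            parent[a] = parent.get(parent[a], parent[a])
            a = parent[a]
        return a

    for i, j in spec.edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = {find(i) for i in parent}
    return GroundTruth(n_end=n_end, n_bif=n_bif, n_cross=n_cross,
                       total_length_mm=length, n_components=len(roots))


def _capsule_union(shape, nodes, edges, radii) -> np.ndarray:
    """Voxels whose centre is within radius of any edge segment."""
    out = np.zeros(shape, bool)
    nodes = np.asarray(nodes, float)
    for (i, j), r in zip(edges, radii):
        a, b = nodes[i], nodes[j]
        lo = np.floor(np.minimum(a, b) - r).astype(int)
        hi = np.ceil(np.maximum(a, b) + r).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(hi <= lo):
            continue
        grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        p = np.stack([g.astype(float) for g in grids], axis=-1)
        ab = b - a
        denom = float(ab @ ab) or 1.0
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        d = np.linalg.norm(p - (a + t[..., None] * ab), axis=-1)
        out[tuple(slice(l, h) for l, h in zip(lo, hi))] |= d <= r
    return out


def rasterize_phantom(spec: PhantomSpec):
    """Rasterize a phantom: returns (DopplerVolume, RegionMask, GroundTruth).

    The region mask covers the full grid.  Ground truth comes from the graph
    alone.  Artefacts requested in the spec are NOT applied here; use
    :func:`add_artifacts` so the clean and corrupted volumes are both
    available.
    """
    vessel = _capsule_union(spec.shape, spec.nodes, spec.edges, spec.radii)
    intens = np.full(spec.shape, spec.background_intensity, dtype=np.uint8)
    intens[vessel] = spec.vessel_intensity
    vol = DopplerVolume(intensities=intens, spacing=spec.spacing)
    roi = RegionMask(mask=np.ones(spec.shape, bool), spacing=spec.spacing)
    return vol, roi, _graph_truth(spec)


def add_artifacts(vol: DopplerVolume, spec: PhantomSpec) -> DopplerVolume:
    """Overlay stripe planes, solid blobs and isolated voxels on a volume.

    Stripes are one-voxel-thick supra-threshold planes (the stripe-like
    Doppler artefacts seen in vivo); blobs are small solid balls that
    provoke cluster voxels after thinning; isolated voxels are placed with a
    one-voxel clearance from existing signal so they survive as single
    skeleton voxels.  Deterministic for a fixed ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    intens = vol.intensities.copy()
    level = spec.vessel_intensity
    shape = np.asarray(vol.shape)
    for _ in range(spec.n_stripes):
        axis = int(rng.integers(3))
        idx = int(rng.integers(2, shape[axis] - 2))
        sl = [slice(None)] * 3
        sl[axis] = idx
        intens[tuple(sl)] = level
    for _ in range(spec.n_blobs):
        # hollow shells: thinning cannot reduce a closed surface to a curve,
        # so these leave the cluster-class voxels seen with hollow signal
        r = int(rng.integers(4, 6))
        c = rng.integers(r + 1, shape - r - 1)
        zz, yy, xx = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
        d2 = zz ** 2 + yy ** 2 + xx ** 2
        shell = (d2 <= r ** 2) & (d2 >= (r - 2) ** 2)
        region = tuple(slice(int(ci) - r, int(ci) + r + 1) for ci in c)
        intens[region][shell] = level
    placed = 0
    attempts = 0
    while placed < spec.n_isolated and attempts < 10000:
        attempts += 1
        c = tuple(int(v) for v in rng.integers(1, shape - 1))
        nb = intens[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 2]
        if (nb > 0).any():
            continue
        intens[c] = level
        placed += 1
    return DopplerVolume(intensities=intens, spacing=vol.spacing)


# ---------------------------------------------------------------------------
# canonical phantom constructors


def tube_spec(length: int = 40, radius: float = 3.0, axis: int = 2,
              spacing=(1.0, 1.0, 1.0), margin: int = 8) -> PhantomSpec:
    """A straight axis-aligned tube of given centreline length (voxels)."""
    side = int(2 * (radius + margin) + 1)
    shape = [side, side, side]
    shape[axis] = length + 2 * margin
    c = [s // 2 for s in shape]
    a, b = list(c), list(c)
    a[axis] = margin
    b[axis] = margin + length
    return PhantomSpec(shape=tuple(shape), nodes=(tuple(map(float, a)), tuple(map(float, b))),
                       edges=((0, 1),), radii=(radius,), spacing=tuple(spacing))


def y_spec(radius: float = 3.0, arm: int = 20, spacing=(1.0, 1.0, 1.0)) -> PhantomSpec:
    """A single planar bifurcation: one stem splitting into two 45-degree arms."""
    m = int(radius + 5)
    shape = (2 * m + 9, 2 * arm + 2 * m + 8, 2 * arm + 2 * m + 8)
    z = shape[0] // 2
    jy, jx = arm + m + 3, arm + m + 3
    nodes = (
        (float(z), float(jy), float(jx - arm)),   # stem end
        (float(z), float(jy), float(jx)),          # junction
        (float(z), float(jy - arm), float(jx + arm)),
        (float(z), float(jy + arm), float(jx + arm)),
    )
    return PhantomSpec(shape=shape, nodes=nodes,
                       edges=((0, 1), (1, 2), (1, 3)),
                       radii=(radius,) * 3, spacing=tuple(spacing))


def _seg_min_dist(a0, a1, b0, b1, samples: int = 25) -> float:
    best = math.inf
    A, B = a1 - a0, b1 - b0
    for p0, d0, q0, dq in ((a0, A, b0, B), (b0, B, a0, A)):
        denom = float(dq @ dq) or 1.0
        for t in np.linspace(0.0, 1.0, samples):
            p = p0 + t * d0
            s = float(np.clip(((p - q0) @ dq) / denom, 0.0, 1.0))
            best = min(best, float(np.linalg.norm(p - (q0 + s * dq))))
    return best


def random_tree_spec(seed: int, n_bifurcations: int = 5, arm_steps: int = 12,
                     radius: float = 3.0, shape=(110, 110, 110),
                     spacing=(1.0, 1.0, 1.0), max_tries: int = 400) -> PhantomSpec:
    """A random vessel tree from the clean-junction family.

    Nodes sit on integer lattice coordinates; every bifurcation's
    (incoming, child, child) direction triple comes from the frozen
    clean-junction catalogue, and arms keep a clearance of 2*radius + 4
    voxels from non-incident arms, so the rasterized tree thins to a
    skeleton whose endpoint and bifurcation voxel counts equal the graph
    ground truth exactly (for radius >= 3 and arm_steps >= 10).
    """
    by_parent: dict[tuple[int, int, int], list] = {}
    for dp, c1, c2 in CLEAN_JUNCTION_TRIPLES:
        by_parent.setdefault(dp, []).append((np.array(c1), np.array(c2)))
    roots = sorted(by_parent)
    rng = np.random.default_rng(seed)
    margin = radius + 4
    lo = np.full(3, margin)
    hi = np.asarray(shape) - 1 - margin
    clearance = 2 * radius + 4
    for _ in range(max_tries):
        center = np.asarray(shape) // 2
        d0 = np.array(roots[rng.integers(len(roots))])
        nodes = [center.copy(), center + d0 * arm_steps]
        edges = [(0, 1)]
        tips = [(1, d0)]
        failed = False
        bifs = 0
        while bifs < n_bifurcations and not failed:
            ni, d = tips.pop(int(rng.integers(len(tips))))
            pairs = by_parent[tuple(d)]
            placed = False
            for oi in rng.permutation(len(pairs)):
                c1, c2 = pairs[oi]
                ok = True
                for c in (c1, c2):
                    npos = nodes[ni] + c * arm_steps
                    if np.any(npos < lo) or np.any(npos > hi):
                        ok = False
                        break
                    for (i, j) in edges:
                        if ni in (i, j):
                            continue
                        if _seg_min_dist(nodes[ni].astype(float), npos.astype(float),
                                         nodes[i].astype(float),
                                         nodes[j].astype(float)) < clearance:
                            ok = False
                            break
                    if not ok:
                        break
                    for m, nn in enumerate(nodes):
                        if m != ni and np.linalg.norm(npos - nn) < clearance:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                for c in (c1, c2):
                    nodes.append(nodes[ni] + c * arm_steps)
                    edges.append((ni, len(nodes) - 1))
                    tips.append((len(nodes) - 1, c))
                placed = True
                break
            if not placed:
                failed = True
            else:
                bifs += 1
        if failed:
            continue
        return PhantomSpec(
            shape=tuple(int(s) for s in shape),
            nodes=tuple(tuple(float(v) for v in n) for n in nodes),
            edges=tuple(edges),
            radii=(radius,) * len(edges),
            spacing=tuple(spacing),
            rng_seed=int(seed),
        )
    raise RuntimeError(
        f"could not place a {n_bifurcations}-bifurcation clean tree in grid {shape}")


# ---------------------------------------------------------------------------
# synthetic cohorts

#: Median anchor values of each quantity at 7, 9 and 11 weeks GA in the
#: uncomplicated stratum.  Characteristic anchors are density ratios (per
#: cm3 uPVV) typical of first-trimester utero-placental networks multiplied
#: by the uPVV anchors; PV/uPVV anchors are typical first-trimester volumes.
COHORT_ANCHORS: dict[str, tuple[float, float, float]] = {
    "pv_cm3": (10.0, 30.0, 60.0),
    "upvv_cm3": (0.5, 1.5, 3.0),
    "n_end": (145.0, 245.0, 339.0),
    "n_vessel": (470.0, 880.0, 1270.0),
    "n_bif": (68.0, 142.0, 219.0),
    "n_cross": (17.0, 50.0, 85.0),
    "total_length_mm": (389.0, 887.0, 1478.0),
    "avg_vessel_length_mm": (1.5, 1.5, 1.5),
    "avg_thickness_mm": (1.2, 1.5, 1.8),
}

_CHAR_KEYS = ("n_end", "n_vessel", "n_bif", "n_cross",
              "total_length_mm", "avg_vessel_length_mm", "avg_thickness_mm")


def _quadratic_through(anchors, ga_anchor=(7.0, 9.0, 11.0)):
    """Coefficients (c0, c1, c2) of the quadratic through three anchors."""
    V = np.vander(np.asarray(ga_anchor, float), 3, increasing=True)
    return np.linalg.solve(V, np.asarray(anchors, float))


def synth_cohort(
    n_subjects: int = 214,
    seed: int = 0,
    ga_weeks=(7.0, 9.0, 11.0),
    attendance=(0.44, 0.80, 0.60),
    prevalence: float = 0.252,
    effect_characteristics: float = 0.9,
    effect_upvv: float = 0.8,
    effect_pv: float = 0.85,
    sigma_subject: float = 0.30,
    sigma_visit: float = 0.25,
    ga_jitter_weeks: float = 0.5,
) -> pd.DataFrame:
    """Simulate a longitudinal cohort of the seven characteristics + volumes.

    Per subject-visit rows: each quantity follows a quadratic-in-GA median
    trajectory (anchored at :data:`COHORT_ANCHORS`), scaled by a shared
    subject-level log-normal random intercept (sd ``sigma_subject`` on the
    log scale) and per-visit log-normal noise (sd ``sigma_visit``).
    Subjects in the complication stratum (drawn with ``prevalence``) have
    characteristics multiplied by ``effect_characteristics`` and volumes by
    ``effect_upvv`` / ``effect_pv``; the stronger volume reduction makes
    density ratios higher in the complicated stratum, as observed clinically.
    Density ratios are derived exactly from the simulated values.
    Deterministic for a fixed seed.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    rng = np.random.default_rng(seed)
    coefs = {k: _quadratic_through(v) for k, v in COHORT_ANCHORS.items()}
    rows = []
    for subj in range(n_subjects):
        complication = int(rng.random() < prevalence)
        nulliparous = int(rng.random() < 0.57)
        ivf = int(rng.random() < 0.407)
        male = int(rng.random() < 0.495)
        intercept = rng.normal(0.0, sigma_subject)
        for week, att in zip(ga_weeks, attendance):
            if rng.random() > att:
                continue
            ga = week + rng.uniform(-ga_jitter_weeks, ga_jitter_weeks)
            noise = rng.normal(0.0, sigma_visit, size=len(COHORT_ANCHORS))
            values = {}
            for (key, c), eps in zip(coefs.items(), noise):
                mu = float(np.polynomial.polynomial.polyval(ga, c))
                v = mu * math.exp(intercept + eps)
                if complication:
                    if key == "upvv_cm3":
                        v *= effect_upvv
                    elif key == "pv_cm3":
                        v *= effect_pv
                    else:
                        v *= effect_characteristics
                values[key] = max(v, 1e-9)
            mc = MorphCharacteristics(
                n_end=values["n_end"], n_vessel=values["n_vessel"],
                n_bif=values["n_bif"], n_cross=values["n_cross"],
                total_length_mm=values["total_length_mm"],
                avg_vessel_length_mm=values["avg_vessel_length_mm"],
                avg_thickness_mm=values["avg_thickness_mm"])
            ratios = density_ratios(mc, values["pv_cm3"], values["upvv_cm3"])
            row = {
                "id": f"S{subj:04d}", "subject": subj, "visit_week": week,
                "ga_weeks": ga, "complication": complication,
                "parity_nulliparous": nulliparous, "conception_ivf": ivf,
                "fetal_sex_male": male,
                "pv_cm3": values["pv_cm3"], "upvv_cm3": values["upvv_cm3"],
            }
            row.update({k: values[k] for k in _CHAR_KEYS})
            row.update(ratios.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_lmm_cohort(
    n_subjects: int = 200,
    seed: int = 0,
    beta=(10.0, 2.0, 0.5),
    sigma_subject: float = 2.0,
    sigma_resid: float = 1.0,
    ga_weeks=(7.0, 9.0, 11.0),
    group_effect=(0.0, 0.0, 0.0),
    prevalence: float = 0.25,
) -> pd.DataFrame:
    """Simulate data exactly from the longitudinal mixed model.

    y = b0 + b1*GA + b2*GA^2 + group*(g0 + g1*GA + g2*GA^2) + u_subject + e,
    with u ~ N(0, sigma_subject^2) and e ~ N(0, sigma_resid^2).  Used for
    parameter-recovery and type-I-error validation of the trajectory model;
    the full cohort generator (:func:`synth_cohort`) instead uses the
    multiplicative log-normal noise appropriate for the skewed positive
    characteristics.
    """
    rng = np.random.default_rng(seed)
    b0, b1, b2 = beta
    g0, g1, g2 = group_effect
    subj = np.repeat(np.arange(n_subjects), len(ga_weeks))
    ga = np.tile(np.asarray(ga_weeks, float), n_subjects)
    group = (rng.random(n_subjects) < prevalence).astype(int)[subj]
    u = rng.normal(0.0, sigma_subject, n_subjects)[subj]
    e = rng.normal(0.0, sigma_resid, len(subj))
    y = (b0 + b1 * ga + b2 * ga ** 2
         + group * (g0 + g1 * ga + g2 * ga ** 2) + u + e)
    return pd.DataFrame({"subject": subj, "ga_weeks": ga, "value": y,
                         "complication": group})
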