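"""Synthetic cohort generator for the ALS phenotype classification study.

The study's clinical cohort (15 neurological controls and 91 ALS
patients in four phenotypes) is private, so every downstream stage is
exercised on simulated subjects with the qualitative group structure
the analysis assumes:

* disassortative AD-weighted connectomes and globally lower network
  density/efficiency in ALS-FTD;
* reduced WM fractal complexity in ALS-FTD, increased GM fractal
  complexity in ALS-Cl and ALS-FTD;
* elevated radial/mean diffusivity and reduced fractional anisotropy
  along the corticospinal tract in patients, more on the right and at
  rostral ROI levels;
* clinical decline (ALSFRS-R and subscores) scaled by a per-group
  severity factor, with controls carrying the neutral convention
  (ALSFRS-R 48, symptom duration 0, El Escorial 0, progression rate 0);
* occasional missing CST values, mimicking truncated virtual tracts.

Effect sizes are *qualitative* choices of this package (the source
study publishes directions, not magnitudes).  Setting every effect
multiplier to 1 (``CohortSpec.null()``) makes the five groups
statistically exchangeable, which pins downstream classifiers to
chance level.

Two generation modes exist.  ``fast`` (default) samples the graph and
FD feature blocks directly from the group-conditioned parametric model;
``full`` synthesizes tissue volumes (stochastic branching-tube WM
inside a roughened GM shell) and modular connectivity matrices, and
derives those blocks through the morphometry and network modules.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import schema
from .graphs import ConnectivityMatrix
from .volume import BinaryVolume

__all__ = [
    "PhenotypeLabel",
    "CohortSpec",
    "SubjectRecord",
    "CohortBundle",
    "generate_phantom",
    "generate_tissue_volumes",
    "generate_connectivity_matrix",
    "generate_cst_features",
    "generate_clinical_features",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

# Re-export: phantoms are part of this module's public surface.
from .phantoms import generate_phantom  # noqa: E402  (re-export)


@dataclass(frozen=True)
class PhenotypeLabel:
    """One of the five diagnostic classes, coded 0-4."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in range(5):
            raise ValueError(f"phenotype code must be 0..4, got {self.code}")

    @property
    def name(self) -> str:
        return schema.PHENOTYPE_NAMES[self.code]

    @classmethod
    def from_name(cls, name: str) -> "PhenotypeLabel":
        if name not in schema.PHENOTYPE_CODES:
            raise ValueError(f"unknown phenotype {name!r}")
        return cls(schema.PHENOTYPE_CODES[name])


# ---------------------------------------------------------------------------
# Effect configuration
#
# block -> group -> multiplier.  Multiplier 1 means "distributed like the
# control group"; defaults encode the qualitative directions above.
# The assortativity entry is a signed multiplier on the target
# assortativity of the AD network (negative = disassortative) rather
# than a magnitude scale.
# ---------------------------------------------------------------------------

DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    # Connectome magnitude scale (edge probability / density / efficiency).
    "graph": {"ALS-FTD": 0.82, "ALS-Cl": 0.97, "ALS-CST+": 0.96, "ALS-CST-": 0.96},
    # Signed scale on the AD-network assortativity target (base +0.15).
    "assortativity_ad": {"ALS-CST+": 0.55, "ALS-CST-": 0.45,
                         "ALS-Cl": 0.50, "ALS-FTD": -0.80},
    # WM structural complexity (branching density / skeleton FD).
    "wm_complexity": {"ALS-FTD": 0.55},
    # GM boundary roughness (surface convolution / GM FD).
    "gm_complexity": {"ALS-Cl": 1.30, "ALS-FTD": 1.45},
    # CST DTI metric scales.
    "cst_fa": {"ALS-CST+": 0.88, "ALS-CST-": 0.92, "ALS-Cl": 0.93, "ALS-FTD": 0.90},
    "cst_ad": {"ALS-CST+": 0.97, "ALS-CST-": 0.98, "ALS-Cl": 0.97, "ALS-FTD": 0.94},
    "cst_rd": {"ALS-CST+": 1.25, "ALS-CST-": 1.15, "ALS-Cl": 1.15, "ALS-FTD": 1.20},
    "cst_md": {"ALS-CST+": 1.10, "ALS-CST-": 1.07, "ALS-Cl": 1.08, "ALS-FTD": 1.10},
    # Clinical severity (multiplier - 1 drives functional decline).
    "clinical": {"ALS-CST+": 1.55, "ALS-CST-": 1.50, "ALS-Cl": 1.70, "ALS-FTD": 1.90},
}


@dataclass
class CohortSpec:
    """Cohort composition, effect configuration and randomization seed."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(schema.DEFAULT_GROUP_SIZES))
    effect_config: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_EFFECTS))
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in schema.PHENOTYPE_CODES:
                raise ValueError(f"unknown group {g!r}")
            if self.group_sizes[g] < 1:
                raise ValueError(f"group size for {g!r} must be >= 1")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        for block, per_group in self.effect_config.items():
            for g, v in per_group.items():
                if not np.isfinite(v):
                    raise ValueError(f"effect {block}/{g} must be finite")
                if block != "assortativity_ad" and v <= 0:
                    raise ValueError(
                        f"magnitude effect {block}/{g} must be positive")

    def effect(self, block: str, group: str) -> float:
        return float(self.effect_config.get(block, {}).get(group, 1.0))

    @classmethod
    def null(cls, **kwargs) -> "CohortSpec":
        """Effect-free configuration: all five groups exchangeable."""
        kwargs.setdefault("effect_config", {})
        return cls(**kwargs)

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


def _as_group(group: PhenotypeLabel | str | int) -> str:
    if isinstance(group, PhenotypeLabel):
        return group.name
    if isinstance(group, int):
        return PhenotypeLabel(group).name
    if group not in schema.PHENOTYPE_CODES:
        raise ValueError(f"unknown group {group!r}")
    return group


# ---------------------------------------------------------------------------
# Tissue volume synthesis (full mode)
# ---------------------------------------------------------------------------

def _grow_branching_tubes(rng: np.random.Generator, shape, center, radii,
                          branch_prob: float) -> np.ndarray:
    """Stochastic branching-tube network confined to an ellipsoid."""
    grid = np.zeros(shape, dtype=bool)
    center = np.asarray(center, float)
    radii = np.asarray(radii, float)
    # Eight fixed seed directions (toward the corners) keep both
    # hemispheres populated; per-run jitter randomizes the details.
    base_dirs = np.array([[sx, sy, sz] for sx in (-1, 1)
                          for sy in (-1, 1) for sz in (-1, 1)], float)
    base_dirs /= np.linalg.norm(base_dirs, axis=1, keepdims=True)
    tips = [(center.copy(), d + rng.normal(scale=0.15, size=3))
            for d in base_dirs]
    max_tips = 96
    for _ in range(140):
        new_tips = []
        for pos, d in tips:
            d = d + rng.normal(scale=0.30, size=3)
            d /= max(np.linalg.norm(d), 1e-9)
            pos = pos + d
            f = (((pos - center) / radii) ** 2).sum()
            if f >= 1.0:
                continue  # tip terminates at the WM/GM interface
            idx = tuple(np.clip(np.round(pos).astype(int), 0,
                                np.array(shape) - 1))
            grid[idx] = True
            new_tips.append((pos, d))
            if len(new_tips) < max_tips and rng.random() < branch_prob:
                dd = d + rng.normal(scale=1.0, size=3)
                dd /= max(np.linalg.norm(dd), 1e-9)
                new_tips.append((pos.copy(), dd))
        tips = new_tips
        if not tips:
            break
    return grid


def generate_tissue_volumes(group: PhenotypeLabel | str, spec: CohortSpec,
                            seed: int, shape: tuple[int, int, int] = (48, 48, 48)
                            ) -> tuple[np.ndarray, np.ndarray]:
    """WM and GM probability maps for one synthetic subject.

    WM is a stochastic branching-tube network inside an ellipsoidal
    core whose branching density scales with the group's
    ``wm_complexity`` multiplier; GM is the shell around the core whose
    boundary roughness scales with ``gm_complexity``.  The two tissues
    are disjoint and meet at the core boundary.
    """
    g = _as_group(group)
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    n = np.array(shape, float)
    center = (n - 1) / 2.0
    outer = 0.46 * n
    inner = 0.33 * n

    branch_prob = 0.10 * spec.effect("wm_complexity", g)
    wm_mask = _grow_branching_tubes(rng, shape, center, inner, branch_prob)
    wm_mask = ndimage.binary_dilation(
        wm_mask, structure=ndimage.generate_binary_structure(3, 1))

    ax = [np.arange(s) for s in shape]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    f_inner = (((xx - center[0]) / inner[0]) ** 2
               + ((yy - center[1]) / inner[1]) ** 2
               + ((zz - center[2]) / inner[2]) ** 2)
    f_outer = (((xx - center[0]) / outer[0]) ** 2
               + ((yy - center[1]) / outer[1]) ** 2
               + ((zz - center[2]) / outer[2]) ** 2)
    gm_mult = spec.effect("gm_complexity", g)
    # Boundary roughness: a smooth envelope perturbation plus a
    # fine-scale component whose amplitude carries the group effect;
    # both GM boundaries (pial and WM-facing) are convoluted.
    coarse = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    coarse /= max(np.abs(coarse).max(), 1e-9)
    fine = ndimage.gaussian_filter(rng.normal(size=shape), sigma=0.7)
    fine /= fine.std()
    rough = 0.08 * coarse + 0.055 * (gm_mult - 0.6) * fine
    gm_mask = (f_inner + rough >= 1.0) & (f_outer + rough <= 1.0)
    gm_mask &= ~wm_mask

    wm_prob = np.clip(ndimage.gaussian_filter(wm_mask.astype(float), 0.6)
                      * 1.4, 0.0, 1.0)
    gm_prob = np.clip(ndimage.gaussian_filter(gm_mask.astype(float), 0.6)
                      * 1.4, 0.0, 1.0)
    # Disjoint foreground after binarization at 0.5: WM wins overlaps.
    gm_prob = np.minimum(gm_prob, 0.98 * (1.0 - wm_prob))
    return wm_prob, gm_prob


# ---------------------------------------------------------------------------
# Connectivity matrix synthesis
# ---------------------------------------------------------------------------

_BASE_WEIGHT = {"FA": 0.45, "AD": 1.10, "RD": 0.45, "MD": 0.70}
_N_NODES = 90  # AAL cortical+subcortical convention
_N_COMMUNITIES = 6


def _assortativity_from_S(deg, edges, S):
    ends = np.concatenate([[deg[a] for a, b in edges], [deg[b] for a, b in edges]])
    mean = ends.mean()
    var = ((ends - mean) ** 2).mean()
    if var == 0:
        return np.nan
    m = len(edges)
    return (S / m - mean ** 2) / var


def generate_connectivity_matrix(group: PhenotypeLabel | str, weighting: str,
                                 spec: CohortSpec, seed: int
                                 ) -> ConnectivityMatrix:
    """One 90-node modular weighted connectome for a synthetic subject.

    A stochastic block model (6 communities) provides the topology; its
    edge probability scales with the group's ``graph`` multiplier, and
    degree-preserving swaps steer the network toward a target degree
    assortativity (positive for controls, negative for ALS-FTD under
    the AD weighting).  Edge weights are metric-scale lognormal values,
    elevated within communities.
    """
    g = _as_group(group)
    if weighting not in schema.GRAPH_WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)
    dens_mult = spec.effect("graph", g)
    p_in, p_out = 0.38 * dens_mult, 0.10 * dens_mult

    comm = np.repeat(np.arange(_N_COMMUNITIES), _N_NODES // _N_COMMUNITIES)
    same = comm[:, None] == comm[None, :]
    p = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((_N_NODES, _N_NODES)) < p, k=1)
    adj = upper | upper.T

    # Steer assortativity with degree-preserving swaps (degrees, and
    # therefore the endpoint-degree moments, are swap-invariant, so the
    # Newman coefficient is monotone in S = sum of endpoint products).
    if weighting == "AD":
        target_r = 0.15 * spec.effect("assortativity_ad", g)
    else:
        target_r = 0.12
    edges = [(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(adj, k=1)))]
    deg = adj.sum(axis=1).astype(float)
    S = float(sum(deg[a] * deg[b] for a, b in edges))
    edge_set = set(edges)
    r = _assortativity_from_S(deg, edges, S)
    for _ in range(40 * len(edges)):
        if np.isnan(r) or abs(r - target_r) < 0.015:
            break
        e1, e2 = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            a, b = b, a
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if a == d or c == b or new1 in edge_set or new2 in edge_set:
            continue
        dS = (deg[a] * deg[d] + deg[c] * deg[b]) - (deg[a] * deg[b] + deg[c] * deg[d])
        if (target_r > r and dS <= 0) or (target_r < r and dS >= 0):
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1], edges[e2] = new1, new2
        S += dS
        r = _assortativity_from_S(deg, edges, S)

    w = np.zeros((_N_NODES, _N_NODES))
    base = _BASE_WEIGHT[weighting]
    for a, b in edges:
        bonus = 1.25 if comm[a] == comm[b] else 1.0
        w[a, b] = w[b, a] = base * bonus * rng.lognormal(0.0, 0.15)
    labels = [f"AAL{i + 1:03d}" for i in range(_N_NODES)]
    return ConnectivityMatrix(w, weighting, labels)


# ---------------------------------------------------------------------------
# Sampled feature blocks
# ---------------------------------------------------------------------------

# Baseline (mean, relative SD) for the connectome metrics in fast mode.
_GRAPH_BASE: dict[str, tuple[float, float]] = {
    "Assortativity": (0.12, 0.25),
    "Density": (0.30, 0.06),
    "Mean_clustering_coefficient": (0.42, 0.06),
    "Transitivity": (0.46, 0.06),
    "Global_efficiency": (0.55, 0.05),
    "Mean_local_efficiency": (0.60, 0.05),
    "Modularity": (0.40, 0.07),
    "Modularity_Louvian": (0.42, 0.07),
    "Characteristic_path_length": (2.10, 0.06),
    "Mean_nodal_betweenness": (60.0, 0.10),
    "Mean_edge_betweenness": (12.0, 0.10),
    "Normalized path length": (1.06, 0.04),
    "Normalized clustering": (1.12, 0.05),
    "Mean_degree": (27.0, 0.06),
}
# Metrics that scale with network density/efficiency ("magnitude" metrics).
_GRAPH_SCALED = {"Density", "Mean_clustering_coefficient", "Transitivity",
                 "Global_efficiency", "Mean_local_efficiency", "Mean_degree"}
# Metrics that move inversely with density (sparser = longer paths).
_GRAPH_INVERSE = {"Characteristic_path_length", "Mean_nodal_betweenness",
                  "Mean_edge_betweenness"}


def sample_graph_features(group: PhenotypeLabel | str, spec: CohortSpec,
                          seed: int) -> dict[str, float]:
    """Fast-mode stand-in for matrix synthesis + network analysis."""
    g = _as_group(group)
    rng = np.random.default_rng(seed)
    mult = spec.effect("graph", g)
    block: dict[str, float] = {}
    for name in schema.graph_feature_names():
        metric, weighting = name.rsplit("_", 1)
        if metric == "Mean_degree":
            metric = "Mean_degree"
        if metric == "Small world index":
            lam = block[f"Normalized path length_{weighting}"]
            gam = block[f"Normalized clustering_{weighting}"]
            block[name] = gam / lam
            continue
        if metric == "Assortativity":
            base, rel = _GRAPH_BASE[metric]
            target = 0.15 * spec.effect("assortativity_ad", g) \
                if weighting == "AD" else base
            block[name] = float(rng.normal(target, 0.03))
            continue
        base, rel = _GRAPH_BASE[metric]
        mean = base
        if metric in _GRAPH_SCALED:
            mean = base * mult
        elif metric in _GRAPH_INVERSE:
            mean = base / mult
        block[name] = float(rng.normal(mean, rel * base))
    return block


_FD_BASE = {("WM", "Gen"): 2.50, ("WM", "surf"): 2.30, ("WM", "skel"): 2.25,
            ("GM", "Gen"): 2.60, ("GM", "surf"): 2.45, ("GM", "skel"): 2.30}
_FD_SD = 0.05
_FD_SLOPE = 0.30  # FD shift per unit of (complexity multiplier - 1)


def sample_fd_features(group: PhenotypeLabel | str, spec: CohortSpec,
                       seed: int) -> dict[str, float]:
    """Fast-mode stand-in for volume synthesis + FD morphometry (20 values)."""
    g = _as_group(group)
    rng = np.random.default_rng(seed)
    block: dict[str, float] = {}
    for tissue in ("WM", "GM"):
        mult = spec.effect(
            "wm_complexity" if tissue == "WM" else "gm_complexity", g)
        for rep in schema.FD_REPRESENTATIONS:
            mean = _FD_BASE[(tissue, rep)] + _FD_SLOPE * (mult - 1.0)
            l = float(rng.normal(mean, _FD_SD))
            r = float(rng.normal(mean, _FD_SD))
            w = (l + r) / 2.0 + float(rng.normal(0.0, _FD_SD / 4))
            block[f"FD_{tissue}_{rep}_L"] = min(l, 3.0)
            block[f"FD_{tissue}_{rep}_R"] = min(r, 3.0)
            block[f"FD_{tissue}_{rep}_W"] = min(w, 3.0)
    sev = spec.effect("clinical", g) - 1.0
    bpf_wm = float(rng.normal(34.0 - 2.0 * sev, 1.2))
    bpf_gm = float(rng.normal(44.0 - 1.5 * sev, 1.2))
    block["BPF_WM"] = bpf_wm
    block["BPF_GM"] = min(bpf_gm, 100.0 - bpf_wm)
    return block


_CST_BASE = {"FA": 0.55, "AD": 1.10, "RD": 0.45, "MD": 0.70}
#: Rostrocaudal involvement weights (rostral levels more affected).
_LEVEL_WEIGHT = {"CP": 0.80, "PLIC": 0.90, "CSoLV": 1.15, "subPMC": 1.05}
#: Right hemisphere more affected than left.
_HEMI_WEIGHT = {"Right": 1.0, "Left": 0.6}


def generate_cst_features(group: PhenotypeLabel | str, spec: CohortSpec,
                          seed: int) -> dict[str, float]:
    """The 32 CST ROI DTI values; masked entries are NaN.

    Group effects are multiplicative deviations from the control
    baseline, weighted by hemisphere (right > left) and ROI level
    (rostral > caudal); with probability ``spec.missing_rate`` a value
    is masked, emulating truncated virtual tracts.
    """
    g = _as_group(group)
    rng = np.random.default_rng(seed)
    block: dict[str, float] = {}
    for name in schema.cst_feature_names():
        metric, hemi, level = name.split("_")
        base = _CST_BASE[metric]
        mult = spec.effect(f"cst_{metric.lower()}", g)
        eff = 1.0 + (mult - 1.0) * _HEMI_WEIGHT[hemi] * _LEVEL_WEIGHT[level]
        value = float(rng.normal(base * eff, 0.05 * base))
        if rng.random() < spec.missing_rate:
            value = float("nan")
        block[name] = value
    return block


def generate_clinical_features(group: PhenotypeLabel | str, spec: CohortSpec,
                               seed: int) -> dict[str, float]:
    """Demographics and clinical scores (10 values).

    Severity = clinical multiplier - 1.  At severity 0 (controls, or
    any group under the null configuration) the neutral convention
    applies: ALSFRS-R 48 with all subscores 12, zero symptom duration,
    El Escorial 0 and progression rate 0.  Progression rate is defined
    as (48 - ALSFRS-R) / symptom duration.
    """
    g = _as_group(group)
    rng = np.random.default_rng(seed)
    sev = spec.effect("clinical", g) - 1.0
    out: dict[str, float] = {
        "Age": float(np.clip(rng.normal(58.0, 10.0), 25.0, 85.0)),
        "Gender": float(rng.integers(0, 2)),
    }
    if sev <= 0:
        subscores = {s: 12.0 for s in schema.ALSFRS_SUBSCORES}
        out["El_Escorial"] = 0.0
        out["Dur_Symp"] = 0.0
    else:
        subscores = {
            s: float(np.clip(round(rng.normal(12.0 - 5.0 * sev, 1.5)), 0, 12))
            for s in schema.ALSFRS_SUBSCORES
        }
        out["El_Escorial"] = float(rng.integers(1, 5))
        out["Dur_Symp"] = float(max(rng.lognormal(2.9, 0.5), 1.0))
    alsfrs = sum(subscores.values())
    out["ALSFRS-R"] = alsfrs
    out.update(subscores)
    out["Prog_Rate"] = ((48.0 - alsfrs) / out["Dur_Symp"]
                        if out["Dur_Symp"] > 0 else 0.0)
    return {k: out[k] for k in schema.DEMOGRAPHIC_NAMES + schema.CLINICAL_NAMES}


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    label: PhenotypeLabel
    graph_block: dict[str, float]
    cst_block: dict[str, float]
    fd_block: dict[str, float]
    clinical_block: dict[str, float]
    volumes: tuple[np.ndarray, np.ndarray] | None = None
    matrices: dict[str, ConnectivityMatrix] | None = None


@dataclass
class CohortBundle:
    spec: CohortSpec
    records: list[SubjectRecord]
    metadata: dict

    def __len__(self) -> int:
        return len(self.records)


def _child_seed(base_seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(spec: CohortSpec, mode: str = "fast",
                    volume_shape: tuple[int, int, int] = (48, 48, 48),
                    n_nulls: int = 20, keep_raw: bool = False) -> CohortBundle:
    """Generate one synthetic cohort (default composition: 106 subjects).

    ``fast`` mode samples the graph and FD blocks from the parametric
    group model; ``full`` mode synthesizes volumes and matrices and
    computes those blocks through :mod:`alspheno.fractal` and
    :mod:`alspheno.graphs`.  Identical ``(spec, mode)`` reproduce the
    cohort exactly.
    """
    if mode not in ("fast", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    from .fractal import compute_fd_feature_block
    from .graphs import compute_graph_feature_block

    records: list[SubjectRecord] = []
    idx = 0
    for gname in schema.PHENOTYPE_NAMES:
        count = spec.group_sizes.get(gname, 0)
        code = schema.PHENOTYPE_CODES[gname]
        for k in range(count):
            sid = f"S{idx:03d}"
            cst = generate_cst_features(gname, spec,
                                        _child_seed(spec.seed, code, k, 1))
            clin = generate_clinical_features(gname, spec,
                                              _child_seed(spec.seed, code, k, 2))
            volumes = None
            matrices = None
            if mode == "fast":
                graph = sample_graph_features(gname, spec,
                                              _child_seed(spec.seed, code, k, 3))
                fd = sample_fd_features(gname, spec,
                                        _child_seed(spec.seed, code, k, 4))
            else:
                wm, gm = generate_tissue_volumes(
                    gname, spec, _child_seed(spec.seed, code, k, 5),
                    shape=volume_shape)
                fd = compute_fd_feature_block(wm, gm)
                mats = {
                    w: generate_connectivity_matrix(
                        gname, w, spec, _child_seed(spec.seed, code, k, 6, wi))
                    for wi, w in enumerate(schema.GRAPH_WEIGHTINGS)
                }
                graph = compute_graph_feature_block(
                    mats, seed=_child_seed(spec.seed, code, k, 7),
                    n_nulls=n_nulls)
                if keep_raw:
                    volumes = (wm, gm)
                    matrices = mats
            records.append(SubjectRecord(sid, PhenotypeLabel(code),
                                         graph, cst, fd, clin,
                                         volumes, matrices))
            idx += 1
    return CohortBundle(spec=spec, records=records,
                        metadata={"mode": mode,
                                  "fast_fd": mode == "fast",
                                  "n_subjects": len(records)})


# ---------------------------------------------------------------------------
# Serialization: CSV blocks + optional NIfTI volumes / dense matrix files,
# tied together by a manifest.
# ---------------------------------------------------------------------------

def save_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = {
        "graph": "graph_block", "cst": "cst_block",
        "fd": "fd_block", "clinical": "clinical_block",
    }
    for fname, attr in blocks.items():
        df = pd.DataFrame([getattr(r, attr) for r in bundle.records],
                          index=[r.subject_id for r in bundle.records])
        df.index.name = "subject_id"
        df.to_csv(out / f"{fname}.csv")
    labels = pd.DataFrame(
        {"label": [r.label.code for r in bundle.records],
         "group": [r.label.name for r in bundle.records]},
        index=[r.subject_id for r in bundle.records])
    labels.index.name = "subject_id"
    labels.to_csv(out / "labels.csv")

    volume_files: dict[str, list[str]] = {}
    matrix_files: dict[str, dict[str, str]] = {}
    for r in bundle.records:
        if r.volumes is not None:
            import nibabel as nib
            names = []
            for tissue, arr in zip(("wm", "gm"), r.volumes):
                name = f"{r.subject_id}_{tissue}.nii.gz"
                nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)),
                         out / name)
                names.append(name)
            volume_files[r.subject_id] = names
        if r.matrices is not None:
            matrix_files[r.subject_id] = {}
            for w, m in r.matrices.items():
                name = f"{r.subject_id}_{w}.txt"
                with open(out / name, "w") as fh:
                    fh.write(" ".join(m.node_labels) + "\n")
                    np.savetxt(fh, m.weights, fmt="%.6g")
                matrix_files[r.subject_id][w] = name
    manifest = {
        "n_subjects": len(bundle),
        "metadata": bundle.metadata,
        "spec": {
            "group_sizes": bundle.spec.group_sizes,
            "effect_config": bundle.spec.effect_config,
            "missing_rate": bundle.spec.missing_rate,
            "seed": bundle.spec.seed,
        },
        "blocks": {k: f"{k}.csv" for k in blocks},
        "labels": "labels.csv",
        "volumes": volume_files,
        "matrices": matrix_files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_cohort(in_dir: str | Path) -> CohortBundle:
    import pandas as pd

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    spec = CohortSpec(**manifest["spec"])
    frames = {k: pd.read_csv(src / v, index_col="subject_id")
              for k, v in manifest["blocks"].items()}
    labels = pd.read_csv(src / manifest["labels"], index_col="subject_id")
    records = []
    for sid in labels.index:
        records.append(SubjectRecord(
            subject_id=sid,
            label=PhenotypeLabel(int(labels.loc[sid, "label"])),
            graph_block=frames["graph"].loc[sid].to_dict(),
            cst_block=frames["cst"].loc[sid].to_dict(),
            fd_block=frames["fd"].loc[sid].to_dict(),
            clinical_block=frames["clinical"].loc[sid].to_dict(),
        ))
    return CohortBundle(spec=spec, records=records,
                        metadata=manifest["metadata"])
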