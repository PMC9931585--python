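"""Synthetic IMC cohort generator.

Emulates the statistical structure of a tissue-microarray IMC study so
that every analysis stage is testable without any real data: per-core
multichannel images with ground-truth segmentation and lineage labels,
planted spatial niches and pairwise attraction/repulsion, five
histological patterns, and clinical outcomes (progression, survival)
statistically linked to planted spatial features.

Cells are placed by a marked point process: a uniform baseline, niche
members clustered around niche centres, and pairwise interaction
applied by bounded displacement toward (or away from) the nearest
heterotypic neighbour.  Each cell is rendered as a filled disc
(truncated at collisions), and each marker's raster is its on-target
mean on the pixels of its target types, the off-target mean elsewhere,
under multiplicative log-normal pixel noise (IMC counts are positive
and right-skewed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .panel import Marker, MarkerPanel
from .phenotype import CombinationRule, TypeRules
from .stacks import CoreImageStack, SegmentationMap
from .tables import HISTOLOGIES, CellTable, ClinicalTable

# histology frequencies of a 416-patient LUAD cohort (lepidic, papillary,
# acinar, micropapillary, solid)
_HISTOLOGY_P = np.array([40, 33, 190, 35, 118]) / 416.0


@dataclass(frozen=True)
class MarkerSignal:
    """Per-marker intensity model: on-target mean, off-target mean and
    log-normal noise dispersion (sigma of log intensity)."""

    on_mean: float = 10.0
    off_mean: float = 0.5
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.on_mean < 0 or self.off_mean < 0 or self.sigma < 0:
            raise ValueError("signal means and sigma must be >= 0")


@dataclass(frozen=True)
class NicheSpec:
    """A planted spatial niche.

    Cells whose type is in ``members`` join the niche with probability
    ``weight`` and are then placed around one of ``n_centers`` niche
    centres with Gaussian spread ``radius`` (pixels).  ``histologies``
    optionally restricts the niche to cores of those patterns.
    """

    name: str
    members: tuple[str, ...]
    weight: float = 0.9
    radius: float = 30.0
    n_centers: int = 1
    histologies: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("niche radius must be > 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("niche weight must lie in [0, 1]")


@dataclass(frozen=True)
class InteractionEffect:
    """Planted pairwise attraction (strength > 0) or repulsion (< 0).

    Each of ``iterations`` rounds displaces every type-A cell by
    ``|strength|`` pixels toward (attraction, stopping at the collision
    distance) or away from (repulsion) its nearest type-B neighbour.
    The induced adjacency excess/deficit is monotone in strength.
    """

    type_a: str
    type_b: str
    strength: float = 2.0
    iterations: int = 30
    histologies: tuple[str, ...] | None = None


@dataclass(frozen=True)
class OutcomeSpec:
    """Links per-core spatial features to clinical outcomes.

    Features are z-scored across the cohort and named ``freq:<type>``
    (cell-type fraction), ``niche:<name>`` (planted niche prevalence) or
    ``mix:<A>|<B>`` (mean number of B cells within 15 px of an A cell).
    Progression follows a logistic model; survival time follows an
    exponential proportional-hazards model with baseline scale in
    months and independent exponential censoring calibrated to the
    requested censoring rate.
    """

    logistic_intercept: float = -1.1
    logistic_coefs: dict[str, float] = field(default_factory=dict)
    hazard_coefs: dict[str, float] = field(default_factory=dict)
    baseline_scale: float = 60.0
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete description of a synthetic cohort."""

    type_proportions: dict[str, float]
    marker_targets: dict[str, tuple[str, ...]]
    n_patients: int = 120
    cores_per_patient: int = 1
    image_size: tuple[int, int] = (256, 256)
    cell_density: float = 40.0  # cells per 10^4 px^2 (~40 matches ~4k cells/mm^2)
    niches: tuple[NicheSpec, ...] = ()
    interactions: tuple[InteractionEffect, ...] = ()
    signal: dict[str, MarkerSignal] = field(default_factory=dict)
    default_signal: MarkerSignal = MarkerSignal()
    functional_targets: dict[str, tuple[str, float]] = field(default_factory=dict)
    outcome_model: OutcomeSpec | None = None
    cell_radius: int = 3
    min_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type proportions sum to {total}, expected 1")
        for m, targets in self.marker_targets.items():
            unknown = [t for t in targets if t not in self.type_proportions]
            if unknown:
                raise ValueError(f"marker {m!r} targets unknown types {unknown}")
        for f, (t, frac) in self.functional_targets.items():
            if t not in self.type_proportions:
                raise ValueError(f"functional marker {f!r} targets unknown type {t!r}")
            if not 0 <= frac <= 1:
                raise ValueError("functional positive fraction must lie in [0, 1]")

    def signal_for(self, marker: str) -> MarkerSignal:
        return self.signal.get(marker, self.default_signal)

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(self.type_proportions)


@dataclass
class CoreSample:
    stack: CoreImageStack
    seg: SegmentationMap
    truth: CellTable
    niche: pd.Series  # planted niche name per cell_id ("" = background)
    features: dict[str, float]  # realized per-core spatial features


@dataclass
class SyntheticCohort:
    cores: list[CoreSample]
    clinical: ClinicalTable
    features: pd.DataFrame  # ground-truth sidecar: per-core realized features
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# Geometry helpers


def _place_cells(
    n: int,
    shape: tuple[int, int],
    anchors: np.ndarray | None,
    anchor_radius: np.ndarray | None,
    min_sep: float,
    margin: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dart-throwing placement with a uniform-grid collision structure.

    ``anchors`` gives, per cell, a niche centre to scatter around
    (NaN row = uniform placement).
    """
    h, w = shape
    cell = max(min_sep, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    pos = np.empty((n, 2))

    def ok(p: np.ndarray) -> bool:
        gi, gj = int(p[0] // cell), int(p[1] // cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in grid.get((gi + di, gj + dj), ()):
                    if np.hypot(*(pos[idx] - p)) < min_sep:
                        return False
        return True

    for i in range(n):
        placed = False
        for _ in range(200):
            if anchors is not None and np.isfinite(anchors[i, 0]):
                p = anchors[i] + rng.normal(0.0, anchor_radius[i], size=2)
                p = np.clip(p, margin, [h - 1 - margin, w - 1 - margin])
            else:
                p = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
            if ok(p):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place cells without overlap; lower cell_density "
                "or min_separation"
            )
        pos[i] = p
        grid.setdefault((int(p[0] // cell), int(p[1] // cell)), []).append(i)
    return pos


def _apply_interactions(
    pos: np.ndarray,
    types: np.ndarray,
    effects: list[InteractionEffect],
    min_sep: float,
    shape: tuple[int, int],
    margin: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = shape
    pos = pos.copy()
    for eff in effects:
        a_idx = np.flatnonzero(types == eff.type_a)
        b_idx = np.flatnonzero(types == eff.type_b)
        if len(a_idx) == 0 or len(b_idx) == 0:
            continue
        step = abs(eff.strength)
        sign = 1.0 if eff.strength > 0 else -1.0
        for _ in range(eff.iterations):
            tree = cKDTree(pos[b_idx])
            dist, nearest = tree.query(pos[a_idx])
            vec = pos[b_idx][nearest] - pos[a_idx]
            norm = np.maximum(dist, 1e-9)[:, None]
            unit = vec / norm
            if sign > 0:
                move = np.minimum(step, np.maximum(dist - min_sep, 0.0))[:, None] * unit
            else:
                move = -step * unit
            pos[a_idx] = pos[a_idx] + move
            pos[a_idx, 0] = np.clip(pos[a_idx, 0], margin, h - 1 - margin)
            pos[a_idx, 1] = np.clip(pos[a_idx, 1], margin, w - 1 - margin)
    # relax residual collisions introduced by displacement
    for _ in range(20):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=min_sep * 0.999)
        if not pairs:
            break
        for i, j in pairs:
            delta = pos[j] - pos[i]
            d = np.hypot(*delta)
            if d < 1e-9:
                delta = rng.normal(size=2)
                d = np.hypot(*delta)
            push = (min_sep - d) / 2 * delta / d
            pos[i] -= push
            pos[j] += push
        pos[:, 0] = np.clip(pos[:, 0], margin, h - 1 - margin)
        pos[:, 1] = np.clip(pos[:, 1], margin, w - 1 - margin)
    return pos


def _disc_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    keep = dy**2 + dx**2 <= radius**2
    return np.column_stack([dy[keep], dx[keep]])


def _paint(
    pos: np.ndarray, radius: int, shape: tuple[int, int]
) -> np.ndarray:
    """Render cells as discs; earlier cells keep contested pixels."""
    lab = np.zeros(shape, dtype=np.int64)
    offsets = _disc_offsets(radius)
    centers = np.round(pos).astype(int)
    for i, (cy, cx) in enumerate(centers, start=1):
        rr = offsets[:, 0] + cy
        cc = offsets[:, 1] + cx
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        rr, cc = rr[keep], cc[keep]
        free = lab[rr, cc] == 0
        lab[rr[free], cc[free]] = i
    # guarantee every cell at least one pixel
    present = np.isin(np.arange(1, len(pos) + 1), np.unique(lab))
    for i in np.flatnonzero(~present):
        cy, cx = centers[i]
        cy = int(np.clip(cy, 0, shape[0] - 1))
        cx = int(np.clip(cx, 0, shape[1] - 1))
        lab[cy, cx] = i + 1
    return lab


# ---------------------------------------------------------------------------
# Core generation


def generate_core(
    spec: SyntheticSpec,
    seed: int,
    core_id: str = "core",
    histology: str | None = None,
) -> CoreSample:
    """Generate one synthetic core: image stack, ground-truth
    segmentation and cell table, plus realized spatial features."""
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    n = max(1, int(round(spec.cell_density * h * w / 1e4)))
    type_names = list(spec.types)
    probs = np.array([spec.type_proportions[t] for t in type_names])
    types = rng.choice(type_names, size=n, p=probs)

    def active(item) -> bool:
        return item.histologies is None or (
            histology is not None and histology in item.histologies
        )

    niches = [nc for nc in spec.niches if active(nc)]
    margin = float(spec.cell_radius)
    anchors = np.full((n, 2), np.nan)
    anchor_radius = np.zeros(n)
    niche_of = np.array([""] * n, dtype=object)
    # niche centres are rejection-sampled so planted niches stay
    # spatially distinct (pairwise separation ~1.5x the summed radii)
    placed_centers: list[tuple[np.ndarray, float]] = []
    centers_by_niche: dict[str, np.ndarray] = {}
    for nc in niches:
        lo = [margin + nc.radius, margin + nc.radius]
        hi = [h - 1 - margin - nc.radius, w - 1 - margin - nc.radius]
        centers = []
        for _ in range(nc.n_centers):
            best = None
            for _try in range(200):
                cand = rng.uniform(lo, hi)
                sep_ok = all(
                    np.hypot(*(cand - c)) >= 1.5 * (nc.radius + r)
                    for c, r in placed_centers
                )
                if sep_ok:
                    best = cand
                    break
                if best is None:
                    best = cand
            centers.append(best)
            placed_centers.append((best, nc.radius))
        centers_by_niche[nc.name] = np.array(centers)
    for i in range(n):
        candidates = [nc for nc in niches if types[i] in nc.members]
        if not candidates:
            continue
        nc = candidates[rng.integers(len(candidates))]
        if rng.random() < nc.weight:
            niche_of[i] = nc.name
            ctr = centers_by_niche[nc.name][rng.integers(nc.n_centers)]
            anchors[i] = ctr
            anchor_radius[i] = nc.radius

    pos = _place_cells(n, (h, w), anchors, anchor_radius, spec.min_separation, margin, rng)
    effects = [e for e in spec.interactions if active(e)]
    if effects:
        pos = _apply_interactions(
            pos, types, effects, spec.min_separation, (h, w), margin, rng
        )

    lab = _paint(pos, spec.cell_radius, (h, w))
    seg = SegmentationMap(core_id, lab)

    # functional positives are planted per cell
    functional = list(spec.functional_targets)
    positive = {}
    for fm, (target_type, frac) in spec.functional_targets.items():
        positive[fm] = (types == target_type) & (rng.random(n) < frac)

    channels: dict[str, np.ndarray] = {}
    cell_count = len(pos)
    for marker, targets in spec.marker_targets.items():
        sig = spec.signal_for(marker)
        if marker in spec.functional_targets:
            on_cell = np.concatenate([[False], positive[marker]])
        else:
            on_cell = np.concatenate(
                [[False], np.isin(types, list(targets))]
            )
        raster = np.where(on_cell[lab], sig.on_mean, sig.off_mean)
        if sig.sigma > 0:
            raster = raster * rng.lognormal(0.0, sig.sigma, size=raster.shape)
        channels[marker] = raster.astype(np.float32)
    stack = CoreImageStack(core_id, channels)

    # ground-truth cell table
    cells = seg.cells
    assert len(cells) == cell_count
    ids = np.array([c.cell_id for c in cells])
    cent = np.array([c.centroid for c in cells])
    n_pixels = np.bincount(lab.ravel(), minlength=cell_count + 1)
    flat = lab.ravel()
    expr = {}
    for name in stack.channel_names:
        sums = np.bincount(flat, weights=stack[name].ravel().astype(float), minlength=cell_count + 1)
        expr[f"expr_{name}"] = sums[ids] / n_pixels[ids]
    pos_cols = {f"pos_{fm}": positive[fm][ids - 1] for fm in functional}
    df = pd.DataFrame(
        {
            "cell_id": ids,
            "core_id": core_id,
            "centroid_row": cent[:, 0],
            "centroid_col": cent[:, 1],
            "lineage": types[ids - 1],
            **expr,
            **pos_cols,
        }
    )
    truth = CellTable(
        df,
        lineages=tuple(type_names) + ("undefined",),
        channels=tuple(stack.channel_names),
        functional=tuple(functional),
    )

    features = _core_features(spec, types, pos, niche_of)
    return CoreSample(
        stack=stack,
        seg=seg,
        truth=truth,
        niche=pd.Series(niche_of[ids - 1], index=pd.Index(ids, name="cell_id")),
        features=features,
    )


_MIX_RADIUS = 15.0


def _core_features(
    spec: SyntheticSpec, types: np.ndarray, pos: np.ndarray, niche_of: np.ndarray
) -> dict[str, float]:
    n = len(types)
    feats = {f"freq:{t}": float((types == t).mean()) for t in spec.types}
    for nc in spec.niches:
        feats[f"niche:{nc.name}"] = float((niche_of == nc.name).mean())
    pairs = {(e.type_a, e.type_b) for e in spec.interactions}
    for a, b in sorted(pairs):
        a_idx = np.flatnonzero(types == a)
        b_idx = np.flatnonzero(types == b)
        if len(a_idx) == 0 or len(b_idx) == 0:
            feats[f"mix:{a}|{b}"] = 0.0
            continue
        tree = cKDTree(pos[b_idx])
        counts = tree.query_ball_point(pos[a_idx], r=_MIX_RADIUS, return_length=True)
        feats[f"mix:{a}|{b}"] = float(np.mean(counts)) - (1.0 if a == b else 0.0)
    return feats


# ---------------------------------------------------------------------------
# Outcome sampling


def sample_outcomes(
    z_features: pd.DataFrame, outcome: OutcomeSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample progression and survival from z-scored per-patient features.

    Progression ~ Bernoulli(logit^-1(intercept + beta . z)); survival
    time is exponential proportional hazards, T = scale * Exp(1) *
    exp(-eta); censoring is an independent exponential calibrated so
    that P(censored) at baseline equals the censoring rate.
    """
    for coef in (outcome.logistic_coefs, outcome.hazard_coefs):
        unknown = [f for f in coef if f not in z_features.columns]
        if unknown:
            raise ValueError(f"outcome model references unplanted features {unknown}")
    n = len(z_features)
    eta_p = outcome.logistic_intercept + sum(
        b * z_features[f] for f, b in outcome.logistic_coefs.items()
    )
    eta_p = np.asarray(eta_p, dtype=float) if np.ndim(eta_p) else np.full(n, eta_p)
    progression = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_p))

    eta_h = sum(b * z_features[f] for f, b in outcome.hazard_coefs.items())
    eta_h = np.asarray(eta_h, dtype=float) if np.ndim(eta_h) else np.full(n, float(eta_h))
    t_event = rng.exponential(scale=outcome.baseline_scale, size=n) * np.exp(-eta_h)
    r = outcome.censoring_rate
    if r > 0:
        t_cens = rng.exponential(scale=outcome.baseline_scale * (1 - r) / r, size=n)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
    else:
        time, event = t_event, np.ones(n, dtype=bool)
    return pd.DataFrame(
        {"progression": progression, "survival_time": time, "event": event},
        index=z_features.index,
    )


# ---------------------------------------------------------------------------
# Cohort generation


def _patient_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = np.where(rng.random(n) < 0.56, "F", "M")
    age = np.clip(rng.normal(65, 10, n), 35, 90).round(1)
    bmi = np.clip(rng.normal(27, 4, n), 16, 45).round(1)
    smoking = np.where(rng.random(n) < 0.9, "smoker", "non-smoker")
    pack_years = np.where(
        smoking == "smoker", np.clip(rng.normal(35, 15, n), 1, 120).round(0), 0.0
    )
    stage = np.where(rng.random(n) < 0.88, "I-II", "III-IV")
    histology = rng.choice(list(HISTOLOGIES), size=n, p=_HISTOLOGY_P)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "smoking": smoking,
            "pack_years": pack_years,
            "stage": stage,
            "histology": histology,
        }
    ).set_index("patient_id", drop=False)


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort: cores, realized-feature sidecar and a
    clinical table whose outcomes follow the spec's outcome model."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    patients = _patient_covariates(spec.n_patients, rng)
    cores: list[CoreSample] = []
    core_rows = []
    for pid in patients.index:
        hist = patients.loc[pid, "histology"]
        for c in range(spec.cores_per_patient):
            core_id = f"{pid}_c{c}"
            core_seed = int(rng.integers(2**31))
            core = generate_core(spec, seed=core_seed, core_id=core_id, histology=hist)
            cores.append(core)
            core_rows.append({"core_id": core_id, "patient_id": pid, **core.features})
    features = pd.DataFrame(core_rows).set_index("core_id")

    feature_cols = [c for c in features.columns if c != "patient_id"]
    per_patient = features.groupby("patient_id")[feature_cols].mean()
    sd = per_patient.std(ddof=1).replace(0.0, 1.0)
    z = (per_patient - per_patient.mean()) / sd
    outcome = spec.outcome_model or OutcomeSpec()
    outcomes = sample_outcomes(z.loc[patients.index], outcome, rng)

    clin = patients.copy()
    clin["core_ids"] = [
        ";".join(f"{pid}_c{c}" for c in range(spec.cores_per_patient))
        for pid in patients.index
    ]
    clin["progression"] = outcomes["progression"].to_numpy()
    clin["survival_time"] = outcomes["survival_time"].round(4).to_numpy()
    clin["event"] = outcomes["event"].to_numpy()
    clinical = ClinicalTable(clin.reset_index(drop=True))
    return SyntheticCohort(cores=cores, clinical=clinical, features=features, spec=spec)


# ---------------------------------------------------------------------------
# Reference conditions


_SIMPLE_TYPES = [
    # (type, marker, priority rank)
    ("Treg", "FOXP3", 1),
    ("Tc", "CD8a", 2),
    ("Th", "CD4", 3),
    ("B cell", "CD20", 4),
    ("NK", "CD94", 5),
    ("Neutrophil", "CD15", 6),
    ("Mast cell", "CD117", 7),
    ("DC", "CD11c", 8),
    ("Endothelial", "CD31", 9),
    ("Fibroblast", "aSMA", 10),
    ("Tumour", "panCK", 11),
]


def simple_conditions(
    n_types: int = 8, proportions: list[float] | None = None
) -> tuple[MarkerPanel, TypeRules, dict[str, float], dict[str, tuple[str, ...]]]:
    """One-marker-per-type study conditions with ``n_types`` cell types.

    Returns (panel, type rules, type proportions, marker targets); the
    default proportions put the structural types (tumour, endothelium)
    at realistic weight by listing types in reverse priority order.
    """
    if not 2 <= n_types <= len(_SIMPLE_TYPES):
        raise ValueError(f"n_types must lie in [2, {len(_SIMPLE_TYPES)}]")
    chosen = _SIMPLE_TYPES[-n_types:]
    panel = MarkerPanel([Marker(m, "lineage", r) for _, m, r in chosen])
    rules = TypeRules({m: t for t, m, _ in chosen})
    if proportions is None:
        raw = np.linspace(1.0, 2.0, n_types)
        raw = raw / raw.sum()
        props = {t: float(p) for (t, _, _), p in zip(chosen, raw)}
    else:
        props = {t: p for (t, _, _), p in zip(chosen, proportions)}
    targets = {m: (t,) for t, m, _ in chosen}
    return panel, rules, props, targets


def luad_marker_targets() -> dict[str, tuple[str, ...]]:
    """On-target type sets of the default LUAD panel, consistent with
    :func:`~imctme.phenotype.luad_type_rules` (monocyte subsets and
    CD163+ macrophages are double-positive)."""
    return {
        "FOXP3": ("Treg",),
        "CD8a": ("Tc",),
        "CD4": ("Th",),
        "CD20": ("B cell",),
        "CD94": ("NK",),
        "CD15": ("Neutrophil",),
        "CD117": ("Mast cell",),
        "CD68": ("Mac CD163-", "Mac CD163+"),
        "CD163": ("Mac CD163+",),
        "CD14": ("Cl Mo", "Int Mo"),
        "CD16": ("Non-Cl Mo", "Int Mo"),
        "CD11c": ("DC",),
        "CD31": ("Endothelial",),
        "aSMA": ("Fibroblast",),
        "panCK": ("Tumour",),
    }


def luad_type_proportions() -> dict[str, float]:
    """Default 16-type composition loosely matching a LUAD TMA cohort:
    ~40% tumour, ~40% immune (macrophages the largest immune class),
    the rest stromal."""
    props = {
        "Tumour": 0.35,
        "Endothelial": 0.08,
        "Fibroblast": 0.06,
        "Mac CD163-": 0.07,
        "Mac CD163+": 0.055,
        "Th": 0.08,
        "Tc": 0.065,
        "B cell": 0.045,
        "Treg": 0.02,
        "NK": 0.02,
        "Neutrophil": 0.035,
        "Cl Mo": 0.03,
        "Int Mo": 0.015,
        "Non-Cl Mo": 0.015,
        "Mast cell": 0.02,
        "DC": 0.04,
    }
    assert abs(sum(props.values()) - 1.0) < 1e-9
    return props


@dataclass
class SpatialSignalCohort:
    """Cohort where the outcome differs only in spatial arrangement."""

    stacks: list[CoreImageStack]
    segs: list[SegmentationMap]
    truths: list[CellTable]
    labels: np.ndarray  # "progression" / "no progression" per core
    patients: np.ndarray  # one patient per core
    covariates: pd.DataFrame  # clinical covariates independent of the label


def generate_spatial_signal_cohort(
    n_cores: int = 120,
    n_positive: int = 30,
    n_types: int = 6,
    image_size: tuple[int, int] = (256, 256),
    cell_density: float = 40.0,
    niche_radius: float = 18.0,
    n_centers: int = 3,
    seed: int = 0,
) -> SpatialSignalCohort:
    """Cohort with class-matched type frequencies and a purely spatial
    class difference.

    Both classes draw cell types from identical proportions; in
    "progression" cores every cell is pulled into one of ``n_centers``
    tight aggregates (a niche over all types), while "no progression"
    cores are spatially uniform.  Cell frequencies therefore carry no
    class signal; only the arrangement does.
    """
    panel, _, props, targets = simple_conditions(n_types)
    base = dict(
        type_proportions=props,
        marker_targets=targets,
        image_size=image_size,
        cell_density=cell_density,
    )
    spec_neg = SyntheticSpec(**base)
    spec_pos = SyntheticSpec(
        **base,
        niches=(
            NicheSpec(
                "aggregate", tuple(props), weight=1.0, radius=niche_radius,
                n_centers=n_centers,
            ),
        ),
    )
    rng = np.random.default_rng(seed)
    labels = np.array(
        ["progression"] * n_positive + ["no progression"] * (n_cores - n_positive)
    )
    rng.shuffle(labels)
    stacks, segs, truths = [], [], []
    for i, lab in enumerate(labels):
        spec = spec_pos if lab == "progression" else spec_neg
        core = generate_core(spec, seed=int(rng.integers(2**31)), core_id=f"core{i:03d}")
        stacks.append(core.stack)
        segs.append(core.seg)
        truths.append(core.truth)
    patients = np.array([f"P{i:04d}" for i in range(n_cores)])
    covariates = _patient_covariates(n_cores, rng)
    covariates.index = patients
    return SpatialSignalCohort(
        stacks=stacks, segs=segs, truths=truths, labels=labels,
        patients=patients, covariates=covariates,
    )
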