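"""Ground-truthed synthetic H&E tiles and cohorts.

Tiles: elliptical hematoxylin-dense nuclei with variable size and
chromatin content on an eosin background, rendered through the
Beer-Lambert model (I = I0 * 10^(-basis @ concentrations)) with Gaussian
pixel noise. A configurable fraction of nuclei is planted as touching
pairs with a controlled center offset, which is what makes segmentation
refinement nontrivial. Ground truth (label mask, centroids, areas, pair
membership) is returned alongside.

Cohorts: per-patient nuclear-area and cellularity samples drawn from
subtype-specific lognormal distributions (five default subtypes spanning
low to extreme-high cellularity, one with pleomorphic nuclear size),
exponential survival with a treatment-dependent hazard confined to the
extreme-high-cellularity subtype, and independent exponential censoring.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .stain import RGBTile, StainBasis
from .survival import LESS_INTENSIVE, MORE_INTENSIVE, SurvivalRecord

__all__ = [
    "TileSimParams",
    "CohortSimParams",
    "SubtypeParams",
    "SyntheticGroundTruth",
    "TissueSample",
    "CohortData",
    "generate_he_tile",
    "generate_reference_tile",
    "generate_cohort",
    "default_subtypes",
]

# GBM median overall survival is ~14.6 months; exponential hazard ln2/median.
GBM_MEDIAN_SURVIVAL_MONTHS = 14.6


@dataclass
class TileSimParams:
    """Rendering parameters for one synthetic H&E tile.

    Radii are equivalent radii (sqrt(area/pi)) drawn lognormal; each
    ellipse has axes a = r*sqrt(q), b = r/sqrt(q) for an axis ratio q.
    Touching pairs are oriented along the line joining their centers with
    center distance overlap_offset * (a1 + a2), producing a single
    thresholded blob with a concave neck. OD units throughout; noise is in
    8-bit gray levels.
    """

    size: int = 512
    n_nuclei: int = 100
    radius_log_mu: float = float(np.log(8.0))
    radius_log_sigma: float = 0.3
    axis_ratio_range: tuple[float, float] = (1.0, 2.0)
    h_od_mean: float = 0.7
    h_od_sd: float = 0.15
    chromatin_sd: float = 0.08
    eosin_bg_od: float = 0.25
    touching_fraction: float = 0.0
    overlap_offset: float = 0.85
    noise_sd: float = 4.0
    background_intensity: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.touching_fraction <= 1):
            raise ValueError("touching_fraction must be in [0, 1]")
        if self.size < 32 or self.n_nuclei < 0:
            raise ValueError("invalid tile size or nucleus count")


@dataclass
class SyntheticGroundTruth:
    """What was actually planted in a tile."""

    label_mask: np.ndarray  # (H, W) int, 0 background, 1..n nuclei
    centroids: np.ndarray  # (n, 2) planted ellipse centers, (x, y)
    areas: np.ndarray  # (n,) rendered pixel areas
    touching_pairs: list[tuple[int, int]]  # label pairs planted as touching


@dataclass
class _Ellipse:
    cx: float
    cy: float
    a: float  # major semi-axis, px
    b: float  # minor semi-axis, px
    theta: float  # orientation, radians


def _sample_ellipse(rng: np.random.Generator, params: TileSimParams) -> tuple[float, float, float]:
    r = rng.lognormal(params.radius_log_mu, params.radius_log_sigma)
    q = rng.uniform(*params.axis_ratio_range)
    return r, r * np.sqrt(q), r / np.sqrt(q)


def _far_from_all(
    cx: float, cy: float, a: float, placed: list[_Ellipse], skip: set[int], margin: float
) -> bool:
    for i, e in enumerate(placed):
        if i in skip:
            continue
        if np.hypot(cx - e.cx, cy - e.cy) <= a + e.a + margin:
            return False
    return True


def generate_he_tile(
    params: TileSimParams, basis: StainBasis | None = None
) -> tuple[RGBTile, SyntheticGroundTruth]:
    """Render a synthetic H&E tile with known nuclei.

    Raises
    ------
    RuntimeError
        If the requested count cannot be placed disjointly after bounded
        rejection sampling (lower the density or nucleus count).
    """
    basis = basis or StainBasis.default_he()
    rng = np.random.default_rng(params.seed)
    size = params.size
    margin = 2.0  # px clearance between non-touching nuclei

    n_pair_nuclei = 2 * int(round(params.touching_fraction * params.n_nuclei / 2))
    n_single = params.n_nuclei - n_pair_nuclei

    ellipses: list[_Ellipse] = []
    pair_labels: list[tuple[int, int]] = []
    max_attempts = 500

    def place_single() -> _Ellipse:
        r, a, b = _sample_ellipse(rng, params)
        for _ in range(max_attempts):
            cx = rng.uniform(a, size - a)
            cy = rng.uniform(a, size - a)
            if _far_from_all(cx, cy, a, ellipses, set(), margin):
                return _Ellipse(cx, cy, a, b, rng.uniform(0, np.pi))
        raise RuntimeError(
            "could not place nucleus after rejection sampling; lower the density"
        )

    for _ in range(n_single):
        ellipses.append(place_single())

    for _ in range(n_pair_nuclei // 2):
        r1, a1, b1 = _sample_ellipse(rng, params)
        r2, a2, b2 = _sample_ellipse(rng, params)
        placed = False
        for _ in range(max_attempts):
            theta = rng.uniform(0, np.pi)
            d = params.overlap_offset * (a1 + a2)
            cx1 = rng.uniform(a1, size - a1)
            cy1 = rng.uniform(a1, size - a1)
            cx2 = cx1 + d * np.cos(theta)
            cy2 = cy1 + d * np.sin(theta)
            if not (a2 <= cx2 <= size - a2 and a2 <= cy2 <= size - a2):
                continue
            if _far_from_all(cx1, cy1, a1, ellipses, set(), margin) and _far_from_all(
                cx2, cy2, a2, ellipses, set(), margin
            ):
                i = len(ellipses)
                # both members oriented along the joining line -> concave neck
                ellipses.append(_Ellipse(cx1, cy1, a1, b1, theta))
                ellipses.append(_Ellipse(cx2, cy2, a2, b2, theta))
                pair_labels.append((i + 1, i + 2))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place touching pair after rejection sampling; "
                "lower the density"
            )

    # rasterize: later labels overwrite in pair overlaps (labels stay distinct)
    label_mask = np.zeros((size, size), dtype=np.int32)
    conc_h = np.zeros((size, size))
    for i, e in enumerate(ellipses, start=1):
        # draw_ellipse's rotation convention points the major axis along
        # (cos t, -sin t) in (x, y); negate so theta means (cos t, +sin t)
        rr, cc = draw_ellipse(
            e.cy, e.cx, e.b, e.a, shape=(size, size), rotation=-e.theta
        )
        label_mask[rr, cc] = i
        od_n = max(rng.normal(params.h_od_mean, params.h_od_sd), 0.2)
        texture = rng.normal(0.0, params.chromatin_sd, size=len(rr))
        conc_h[rr, cc] = np.maximum(od_n + texture, 0.05)

    conc_e = np.full((size, size), params.eosin_bg_od)
    conc = np.stack([conc_h, conc_e, np.zeros_like(conc_h)], axis=-1)
    od = np.einsum("ij,hwj->hwi", basis.vectors, conc)
    intensity = params.background_intensity * np.power(10.0, -od)
    intensity = intensity + rng.normal(0.0, params.noise_sd, size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    counts = np.bincount(label_mask.ravel(), minlength=len(ellipses) + 1)
    truth = SyntheticGroundTruth(
        label_mask=label_mask,
        centroids=np.array([[e.cx, e.cy] for e in ellipses]),
        areas=counts[1:].astype(float),
        touching_pairs=pair_labels,
    )
    return RGBTile(pixels=pixels), truth


def generate_reference_tile(seed: int = 12345, size: int = 512) -> RGBTile:
    """The synthetic 'gold standard' reference tile for stain normalization.

    A well-stained, highly cellular tile at a fixed seed. The reference
    must be at least as cellular as typical input tiles: per-channel
    quantile matching maps an input's darkest pixels onto the reference's
    darkest quantiles, so if the reference had *fewer* nuclear pixels than
    the input, the input's dimmest nuclei would land on reference
    background values and wash out. Pathology practice is the same — the
    gold standard is a well-stained, cellular section.
    """
    params = TileSimParams(
        size=size, n_nuclei=round(130 * (size / 512) ** 2), seed=seed
    )
    tile, _ = generate_he_tile(params)
    return tile


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SubtypeParams:
    """Lognormal feature distributions and treatment effect for one subtype."""

    name: str
    area_log_mu: float
    area_log_sigma: float
    cellularity_log_mu: float
    cellularity_log_sigma: float
    treatment_hazard_ratio: float = 1.0


def default_subtypes() -> list[SubtypeParams]:
    """Five subtypes spanning the cellularity range, one pleomorphic, and
    the extreme-high-cellularity subtype as the only one whose hazard drops
    under the more-intensive regime."""
    ln = np.log
    return [
        SubtypeParams("high-cellularity", ln(200), 0.25, ln(5e-4), 0.30),
        SubtypeParams("low-cellularity", ln(300), 0.25, ln(1e-4), 0.30),
        SubtypeParams("medium-cellularity", ln(250), 0.25, ln(2.5e-4), 0.30),
        SubtypeParams("high-cellularity-pleomorphic", ln(350), 0.60, ln(5e-4), 0.30),
        SubtypeParams(
            "extreme-high-cellularity",
            ln(170),
            0.25,
            ln(1.2e-3),
            0.30,
            # deliberately strong plant (like the 10-sigma cluster plants):
            # at 10 patients/arm under exponential censoring, log-rank power
            # at alpha = 0.05 is ~0.5 for HR 0.3 but >= 0.99 for HR 0.05, so
            # only the latter makes end-to-end detection informative about
            # the pipeline rather than about small-sample test power
            treatment_hazard_ratio=0.05,
        ),
    ]


@dataclass
class CohortSimParams:
    """Cohort-level simulation parameters.

    Baseline hazard corresponds to the ~14.6 month median survival of GBM;
    censoring is an independent exponential (0.01/month gives roughly 15-20%
    censoring). Patients carry a lognormal random effect on their subtype's
    feature medians, and contribute 1-2 tissue sections.
    """

    patients_per_subtype: int = 20
    subtypes: list[SubtypeParams] = field(default_factory=default_subtypes)
    cells_per_tissue: int = 1000
    max_sections_per_patient: int = 2
    patient_effect_sd: float = 0.1
    baseline_hazard: float = float(np.log(2) / GBM_MEDIAN_SURVIVAL_MONTHS)
    censoring_hazard: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtypes) < 2:
            raise ValueError("need at least two subtypes")
        if any(s.treatment_hazard_ratio <= 0 for s in self.subtypes):
            raise ValueError("hazard ratios must be positive")


@dataclass
class TissueSample:
    """Per-nucleus feature values for one synthetic tissue section."""

    tissue_id: str
    patient_id: str
    area: np.ndarray
    cellularity: np.ndarray


@dataclass
class CohortData:
    tissues: list[TissueSample]
    subtype_labels: dict[str, int]  # patient_id -> 1-based planted subtype
    records: list[SurvivalRecord]
    event_times_uncensored: dict[str, float]


def generate_cohort(params: CohortSimParams) -> CohortData:
    """Simulate feature values, subtype labels and survival for a cohort.

    Treatment assignment is a balanced permutation within each subtype.
    The observed time is min(event, censoring); event flag 1 iff the death
    time comes first.
    """
    rng = np.random.default_rng(params.seed)
    tissues: list[TissueSample] = []
    labels: dict[str, int] = {}
    records: list[SurvivalRecord] = []
    uncensored: dict[str, float] = {}

    for s_idx, sub in enumerate(params.subtypes, start=1):
        n = params.patients_per_subtype
        arms = np.array([MORE_INTENSIVE, LESS_INTENSIVE] * ((n + 1) // 2))[:n]
        arms = arms[rng.permutation(n)]
        for p in range(n):
            pid = f"P{s_idx:02d}{p:03d}"
            labels[pid] = s_idx
            area_shift = rng.normal(0.0, params.patient_effect_sd)
            cell_shift = rng.normal(0.0, params.patient_effect_sd)
            n_sections = int(rng.integers(1, params.max_sections_per_patient + 1))
            for s in range(n_sections):
                tissues.append(
                    TissueSample(
                        tissue_id=f"{pid}-T{s}",
                        patient_id=pid,
                        area=rng.lognormal(
                            sub.area_log_mu + area_shift,
                            sub.area_log_sigma,
                            params.cells_per_tissue,
                        ),
                        cellularity=rng.lognormal(
                            sub.cellularity_log_mu + cell_shift,
                            sub.cellularity_log_sigma,
                            params.cells_per_tissue,
                        ),
                    )
                )
            group = str(arms[p])
            hazard = params.baseline_hazard * (
                sub.treatment_hazard_ratio if group == MORE_INTENSIVE else 1.0
            )
            t_event = rng.exponential(1.0 / hazard)
            t_censor = (
                rng.exponential(1.0 / params.censoring_hazard)
                if params.censoring_hazard > 0
                else np.inf
            )
            uncensored[pid] = t_event
            records.append(
                SurvivalRecord(
                    patient_id=pid,
                    time=float(max(min(t_event, t_censor), 1e-9)),
                    event=int(t_event <= t_censor),
                    group=group,
                    subtype=s_idx,
                )
            )
    return CohortData(
        tissues=tissues,
        subtype_labels=labels,
        records=records,
        event_times_uncensored=uncensored,
    )


def null_cohort_params(seed: int = 0) -> CohortSimParams:
    """Cohort with no treatment effect anywhere (all hazard ratios 1)."""
    subs = [replace(s, treatment_hazard_ratio=1.0) for s in default_subtypes()]
    return CohortSimParams(subtypes=subs, seed=seed)
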