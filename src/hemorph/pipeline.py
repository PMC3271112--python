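"""Block decomposition, per-block processing and cohort orchestration.

Whole-slide images are far too large to process at once, so each image is
partitioned into 1k-by-1k blocks (edge blocks truncated) which are
independent units of work. Each block is segmented with a margin of
surrounding context so nuclei straddling a block edge are seen whole; a
nucleus is owned by the block containing its centroid, and duplicate
margin detections are removed by rounded-global-centroid identity.
Aggregated per-nucleus records then flow through cohort normalization,
consensus subtyping and per-subtype survival comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_normalization import (
    FeatureDistribution,
    GlobalBinning,
    average_patient,
    build_global_bins,
    distributions_to_frame,
    remap_tissue,
)
from .morphometry import (
    NucleusRecord,
    compute_cellularity,
    extract_features,
    records_to_frame,
)
from .segmentation import LabelMask, SegmentationConfig, hematoxylin_channel, segment_channel
from .stain import RGBTile, StainBasis
from .subtyping import ConsensusResult, consensus_cluster, select_k
from .survival import LESS_INTENSIVE, MORE_INTENSIVE, SurvivalRecord, logrank_test

__all__ = [
    "BlockSpec",
    "PipelineConfig",
    "tile_image",
    "segment_tissue_image",
    "CohortAnalysis",
    "run_cohort_analysis",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class BlockSpec:
    """One block of the exact, gapless row-major image partition."""

    row: int
    col: int
    row_off: int
    col_off: int
    height: int
    width: int


def tile_image(shape: tuple[int, int], block_size: int = 1024) -> list[BlockSpec]:
    """Partition an H x W image into ceil(H/b) x ceil(W/b) blocks.

    Blocks are row-major; edge blocks are truncated so the union covers
    every pixel exactly once.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1 or block_size < 1:
        raise ValueError("dimensions and block size must be positive")
    blocks = []
    for bi, r0 in enumerate(range(0, h, block_size)):
        for bj, c0 in enumerate(range(0, w, block_size)):
            blocks.append(
                BlockSpec(
                    row=bi,
                    col=bj,
                    row_off=r0,
                    col_off=c0,
                    height=min(block_size, h - r0),
                    width=min(block_size, w - c0),
                )
            )
    return blocks


def segment_tissue_image(
    tile: RGBTile,
    reference: RGBTile,
    tissue_id: str,
    basis: StainBasis | None = None,
    config: SegmentationConfig | None = None,
    block_size: int = 1024,
    margin: int = 50,
    max_block_failure_fraction: float = 0.1,
    return_mask: bool = False,
) -> list[NucleusRecord] | tuple[list[NucleusRecord], LabelMask]:
    """Segment a full tissue image block-by-block and aggregate records.

    Each block is processed on a window expanded by ``margin`` pixels of
    context. A nucleus belongs to the block containing its (global)
    centroid; detections of the same nucleus from neighboring windows are
    deduplicated by rounded global centroid. Cellularity is recomputed per
    block from the owned centroids over the block's true extent. Failing
    blocks are logged and skipped unless more than
    ``max_block_failure_fraction`` of blocks fail.
    """
    config = config or SegmentationConfig()
    h, w = tile.shape
    blocks = tile_image((h, w), block_size)
    seen: set[tuple[str, int, int]] = set()
    records: list[NucleusRecord] = []
    full_mask = np.zeros((h, w), dtype=np.int32) if return_mask else None
    failures = 0
    next_id = 1
    for blk in blocks:
        r0 = max(0, blk.row_off - margin)
        r1 = min(h, blk.row_off + blk.height + margin)
        c0 = max(0, blk.col_off - margin)
        c1 = min(w, blk.col_off + blk.width + margin)
        try:
            window = RGBTile(pixels=tile.pixels[r0:r1, c0:c1], pixel_size=tile.pixel_size)
            hema = hematoxylin_channel(window, reference, basis)
            mask = segment_channel(hema, config)
            block_records = extract_features(mask, hema, tissue_id)
        except Exception:
            log.exception("block (%d, %d) of %s failed", blk.row, blk.col, tissue_id)
            failures += 1
            continue
        owned: list[NucleusRecord] = []
        for rec in block_records:
            gx = rec.centroid_xy[0] + c0
            gy = rec.centroid_xy[1] + r0
            if not (
                blk.col_off <= gx < blk.col_off + blk.width
                and blk.row_off <= gy < blk.row_off + blk.height
            ):
                continue  # owned by a neighboring block
            key = (tissue_id, int(round(gx)), int(round(gy)))
            if key in seen:
                continue
            seen.add(key)
            rec.centroid_xy = (gx, gy)
            owned.append(rec)
        if owned:
            # cellularity over the block's own extent (values pooled per tissue)
            local = np.array(
                [
                    (r.centroid_xy[0] - blk.col_off, r.centroid_xy[1] - blk.row_off)
                    for r in owned
                ]
            )
            tess = compute_cellularity(local, bounds=(blk.width, blk.height))
            for rec, cell in zip(owned, tess.cellularity):
                if full_mask is not None:
                    ys, xs = np.nonzero(mask.labels == rec.nucleus_id)
                    full_mask[ys + r0, xs + c0] = next_id
                rec.cellularity = float(cell)
                rec.nucleus_id = next_id
                next_id += 1
            records.extend(owned)
    if blocks and failures / len(blocks) > max_block_failure_fraction:
        raise RuntimeError(
            f"{failures}/{len(blocks)} blocks failed for {tissue_id}"
        )
    if return_mask:
        return records, LabelMask(labels=full_mask)
    return records


# ---------------------------------------------------------------------------
# cohort-level orchestration


@dataclass
class CohortAnalysis:
    """Everything the cohort stage computes, in memory."""

    binnings: dict[str, GlobalBinning]
    patient_ids: list[str]
    feature_matrix: np.ndarray  # patients x (n_features * B)
    consensus_results: list[ConsensusResult]
    selected_k: int
    labels: np.ndarray  # recovered subtype per patient, 1..K
    patient_distributions: list[FeatureDistribution]
    survival_table: pd.DataFrame | None = None


def run_cohort_analysis(
    tissue_values: dict[str, dict[str, np.ndarray]],
    tissue_patients: dict[str, str],
    survival_records: list[SurvivalRecord] | None = None,
    features: tuple[str, ...] = ("area", "cellularity"),
    bins: int = 10,
    k_candidates: range | list[int] = range(2, 9),
    resamples: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> CohortAnalysis:
    """Normalize per-tissue feature values, subtype patients, compare survival.

    Parameters
    ----------
    tissue_values : {tissue_id: {feature: values}} raw per-nucleus values.
    tissue_patients : {tissue_id: patient_id} section-to-patient map.
    survival_records : optional clinical records; when given, a pair-wise
        log-rank comparison of treatment-intensity groups is run within
        each *recovered* subtype.
    """
    tissue_ids = sorted(tissue_values)
    patient_ids = sorted({tissue_patients[t] for t in tissue_ids})

    binnings: dict[str, GlobalBinning] = {}
    patient_dists: dict[str, dict[str, FeatureDistribution]] = {
        p: {} for p in patient_ids
    }
    for feat in features:
        pooled = np.concatenate([tissue_values[t][feat] for t in tissue_ids])
        binning = build_global_bins(pooled, bins, feature=feat)
        binnings[feat] = binning
        per_patient: dict[str, list[FeatureDistribution]] = {p: [] for p in patient_ids}
        for t in tissue_ids:
            d = remap_tissue(tissue_values[t][feat], binning, id=t)
            per_patient[tissue_patients[t]].append(d)
        for p in patient_ids:
            patient_dists[p][feat] = average_patient(per_patient[p], id=p)

    X = np.array(
        [
            np.concatenate([patient_dists[p][feat].weights for feat in features])
            for p in patient_ids
        ]
    )
    valid_ks = [k for k in k_candidates if 2 <= k <= len(patient_ids)]
    results = [
        consensus_cluster(
            X,
            K,
            resamples=resamples,
            subsample_fraction=subsample_fraction,
            seed=seed,
        )
        for K in valid_ks
    ]
    if results:
        k = select_k(results)
        labels = next(r for r in results if r.K == k).labels
    else:  # cohort too small to subtype; everything is one group
        k = 1
        labels = np.ones(len(patient_ids), dtype=int)

    table = None
    if survival_records is not None:
        by_patient = {r.patient_id: r for r in survival_records}
        rows = []
        for subtype in range(1, k + 1):
            members = [
                by_patient[p]
                for p, lab in zip(patient_ids, labels)
                if lab == subtype and p in by_patient
            ]
            more = [r for r in members if r.group == MORE_INTENSIVE]
            less = [r for r in members if r.group == LESS_INTENSIVE]
            if more and less and any(r.event for r in members):
                stat, p_val = logrank_test(more, less)
            else:
                stat, p_val = float("nan"), float("nan")
            rows.append(
                {
                    "subtype": subtype,
                    "n": len(members),
                    "n_more_intensive": len(more),
                    "n_less_intensive": len(less),
                    "logrank_statistic": stat,
                    "p_value": p_val,
                }
            )
        table = pd.DataFrame(rows)

    flat_dists = [patient_dists[p][feat] for p in patient_ids for feat in features]
    return CohortAnalysis(
        binnings=binnings,
        patient_ids=patient_ids,
        feature_matrix=X,
        consensus_results=results,
        selected_k=k,
        labels=labels,
        patient_distributions=flat_dists,
        survival_table=table,
    )


# ---------------------------------------------------------------------------
# end-to-end file-based pipeline


@dataclass
class PipelineConfig:
    """File-based run configuration (JSON-serializable)."""

    input_images: list[str]
    reference_image: str
    output_dir: str
    clinical_csv: str | None = None
    block_size: int = 1024
    margin: int = 50
    bins: int = 10
    features: tuple[str, ...] = ("area", "cellularity")
    k_min: int = 2
    k_max: int = 8
    resamples: int = 100
    subsample_fraction: float = 0.8
    seed: int = 0
    stain_basis: list[list[float]] | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        if self.block_size < 64:
            raise ValueError("block_size must be >= 64")
        if self.margin >= self.block_size / 2:
            raise ValueError("margin must be < block_size / 2")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        seg = raw.pop("segmentation", {})
        cfg = cls(**raw)
        cfg.segmentation = SegmentationConfig(**seg)
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            **{k: v for k, v in config.__dict__.items() if k != "segmentation"},
            "segmentation": config.segmentation.__dict__,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> CohortAnalysis:
    """Run images -> features -> normalization -> subtyping -> survival.

    Writes, under the output directory: per-tissue feature CSVs,
    per-patient distribution CSV, global-bin JSON, subtype labels CSV,
    consensus matrix CSV, survival table CSV (when clinical data given)
    and a run manifest.
    """
    from .io import read_tile  # local import to keep pipeline import light

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    basis = (
        StainBasis.from_list(config.stain_basis)
        if config.stain_basis is not None
        else StainBasis.default_he()
    )
    reference = read_tile(config.reference_image)

    from .io import write_mask

    tissue_values: dict[str, dict[str, np.ndarray]] = {}
    tissue_patients: dict[str, str] = {}
    for path in config.input_images:
        tissue_id = Path(path).stem
        tile = read_tile(path)
        records, mask = segment_tissue_image(
            tile,
            reference,
            tissue_id,
            basis=basis,
            config=config.segmentation,
            block_size=config.block_size,
            margin=config.margin,
            return_mask=True,
        )
        write_mask(mask, out / f"mask_{tissue_id}.tif")
        frame = records_to_frame(records)
        frame.to_csv(out / f"features_{tissue_id}.csv", index=False)
        tissue_values[tissue_id] = {
            "area": frame["area"].to_numpy(),
            "cellularity": frame["cellularity"].to_numpy(),
        }
        # tissue ids of the form <patient>-T<k> map to their patient
        tissue_patients[tissue_id] = tissue_id.rsplit("-T", 1)[0]

    survival_records = None
    if config.clinical_csv:
        from .survival import frame_to_records

        survival_records = frame_to_records(pd.read_csv(config.clinical_csv))

    analysis = run_cohort_analysis(
        tissue_values,
        tissue_patients,
        survival_records=survival_records,
        features=config.features,
        bins=config.bins,
        k_candidates=range(config.k_min, config.k_max + 1),
        resamples=config.resamples,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed,
    )

    distributions_to_frame(analysis.patient_distributions).to_csv(
        out / "distributions.csv", index=False
    )
    (out / "global_bins.json").write_text(
        json.dumps({f: b.to_dict() for f, b in analysis.binnings.items()}, indent=2)
    )
    pd.DataFrame(
        {"patient_id": analysis.patient_ids, "subtype": analysis.labels}
    ).to_csv(out / "subtypes.csv", index=False)
    chosen = next(
        (r for r in analysis.consensus_results if r.K == analysis.selected_k), None
    )
    if chosen is not None:
        pd.DataFrame(chosen.consensus).to_csv(out / "consensus.csv", index=False)
    if analysis.survival_table is not None:
        analysis.survival_table.to_csv(out / "survival.csv", index=False)

    manifest = {
        "software_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "selected_k": analysis.selected_k,
        "n_patients": len(analysis.patient_ids),
        "n_tissues": len(tissue_values),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return analysis
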