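"""End-to-end driver: cohort in, group table out.

Stages, in order, per the canonical workflow: preprocessing of each
recording, per-subject clustering of GFP-peak maps, group clustering of
the pooled individual templates, back-fitting of the group classes to
every subject's preprocessed data, temporal parameters, and the
two-group statistics table.  One global seed is fanned out into
per-subject, per-stage substreams keyed by the subject id, so results
are independent of manifest ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as msio
from .backfit import SmoothingSpec, backfit
from .cluster import group_clustering, individual_clustering
from .core import Recording
from .params import SubjectParameters, subject_parameters
from .preprocess import FilterSpec, preprocess
from .stats import GroupStats, build_table

logger = logging.getLogger("mstates")


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the canonical analysis settings:

    1-50 Hz order-4 zero-phase band-pass, decimation by 4, spatial
    smoothing on, 100 uV rejection with +-0.5 s padding, k range 2-10
    with 50 restarts, correlation floor 0.5, smoothing strength 10 with
    window half-size 3, FDR at alpha = 0.05.
    """

    low_hz: float = 1.0
    high_hz: float = 50.0
    filter_order: int = 4
    downsample_factor: int = 4
    spatial_smooth: bool = True
    smooth_strength: float = 1.0
    reject_uv: float = 100.0
    reject_pad_s: float = 0.5
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 50
    corr_floor: float = 0.5
    besag_lambda: float = 10.0
    besag_half_window: int = 3
    alpha: float = 0.05
    seed: int = 0

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(low_hz=self.low_hz, high_hz=self.high_hz, order=self.filter_order)

    def smoothing_spec(self) -> SmoothingSpec:
        return SmoothingSpec(
            lam=self.besag_lambda,
            window_half_size=self.besag_half_window,
            corr_floor=self.corr_floor,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        overrides = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(overrides) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)


def subject_seed(global_seed: int, subject_id: str, stage: str) -> int:
    """Deterministic per-subject, per-stage substream seed (< 2**31).

    Keyed by the subject id, not the manifest position, so reordering
    the manifest does not change any subject's stream.
    """
    key = f"{subject_id}:{stage}".encode()
    return int((int(global_seed) * 2654435761 + zlib.crc32(key)) % (2**31))


@dataclass
class PipelineResult:
    group_templates: object
    group_selection: object
    subjects: list[SubjectParameters]
    stats: GroupStats | None
    failures: list[tuple[str, str]] = field(default_factory=list)


def run_pipeline(
    manifest,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    recordings: dict[str, Recording] | None = None,
) -> PipelineResult:
    """Execute the full workflow over a cohort.

    ``manifest`` is a DataFrame (or path to a CSV) with columns
    subject_id, group, eeg_path[, montage_path]; alternatively
    ``recordings`` maps subject ids to in-memory Recordings and the
    eeg_path column is ignored.  A failing subject is logged and
    skipped; failures are reported in the result.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = msio.read_manifest(manifest)
    if manifest.empty:
        raise ValueError("empty manifest")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    failures: list[tuple[str, str]] = []
    cleaned: dict[str, Recording] = {}
    individual_sets = {}
    montage = None
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        try:
            if recordings is not None:
                rec = recordings[sid]
            else:
                mont = (
                    msio.read_montage(row.montage_path)
                    if getattr(row, "montage_path", None)
                    else None
                )
                rec = msio.read_eeg(row.eeg_path, montage=mont)
            montage = rec.montage
            rec = preprocess(
                rec,
                filter_spec=config.filter_spec(),
                downsample_factor=config.downsample_factor,
                smooth=config.spatial_smooth,
                smooth_strength=config.smooth_strength,
                reject_uv=config.reject_uv,
                reject_pad_s=config.reject_pad_s,
            )
            templates, sel = individual_clustering(
                rec,
                k_min=config.k_min,
                k_max=config.k_max,
                seed=subject_seed(config.seed, sid, "individual"),
                n_restarts=config.n_restarts,
            )
            cleaned[sid] = rec
            individual_sets[sid] = templates
            logger.info("subject %s: k=%d, GEV=%.3f", sid, sel.chosen_k, templates.gev_total)
        except Exception as err:  # noqa: BLE001 - subject-level isolation
            logger.error("subject %s failed: %s", sid, err)
            failures.append((sid, str(err)))

    if len(individual_sets) < 2:
        raise ValueError("fewer than 2 subjects survived preprocessing/clustering")

    ordered_ids = sorted(individual_sets)
    group_templates, group_sel = group_clustering(
        [individual_sets[s] for s in ordered_ids],
        k_min=config.k_min,
        k_max=config.k_max,
        seed=subject_seed(config.seed, "__group__", "group"),
        n_restarts=config.n_restarts,
    )
    if out is not None and montage is not None:
        msio.write_templates(
            group_templates,
            montage,
            out / "group_templates.tsv",
            sidecar={
                "chosen_k": group_sel.chosen_k,
                "votes": group_sel.votes,
                "seed": config.seed,
                "config_hash": config.config_hash(),
            },
        )

    subjects: list[SubjectParameters] = []
    group_of = dict(zip(manifest["subject_id"].astype(str), manifest["group"]))
    for sid in ordered_ids:
        rec = cleaned[sid]
        seq, segments = backfit(rec, group_templates, config.smoothing_spec())
        sp = subject_parameters(
            sid, str(group_of[sid]), seq, segments, rec, group_templates
        )
        subjects.append(sp)
        if out is not None:
            msio.write_labels(
                seq,
                out / f"{sid}_labels.tsv",
                sidecar={"config_hash": config.config_hash(), "seed": config.seed},
            )
            msio.write_segments(segments, out / f"{sid}_segments.tsv")
            sp.table.to_csv(out / f"{sid}_parameters.tsv", sep="\t")

    stats = None
    if manifest["group"].nunique() == 2:
        try:
            stats = build_table(subjects, alpha=config.alpha)
            if out is not None:
                stats.table.to_csv(out / "group_stats.tsv", sep="\t")
                (out / "group_stats.json").write_text(
                    stats.table.reset_index().to_json(orient="records")
                )
        except ValueError as err:
            logger.warning("group statistics skipped: %s", err)

    if out is not None:
        (out / "run.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "config": dataclasses.asdict(config),
                    "config_hash": config.config_hash(),
                    "chosen_k": group_sel.chosen_k,
                    "n_subjects": len(subjects),
                    "failures": failures,
                },
                indent=2,
            )
        )
    return PipelineResult(
        group_templates=group_templates,
        group_selection=group_sel,
        subjects=subjects,
        stats=stats,
        failures=failures,
    )
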