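"""End-to-end orchestration: simulate/load -> extract -> align -> curate ->
attribute -> ordinate, driven by one YAML config whose sections mirror the
numbered processing steps of the reference protocol and whose defaults are
that protocol's printed parameter values.

Every run of the pipeline writes a self-describing bundle: the aligned
matrix with metadata sidecar, per-sample compound lists, attribution
reports (TSV + JSON), ordination coordinates, a JSON-lines stage log with
in/out counts, a config snapshot, and input hashes — identical config and
inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import ordination as ordn
from .align import (AlignedMatrix, CompoundList, join_align, merge_extracts,
                    remove_blank_shared)
from .attribution import AttributionReport, venn_counts
from .features import FeatureParams, Tolerance, extract_features, representatives
from .io import CentroidRun, read_mzml, read_scan_csv
from .simulate import SimConfig, StudyBundle, make_study

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig", "PipelineResult", "StageError",
    "load_config", "save_config", "validate_config",
    "reference_lists", "run_study", "run_pipeline",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CropParams(_Section):
    scan_min: int = 1
    scan_max: int = 1130
    rt_min: float = 0.01
    rt_max: float = 12.51
    mz_min: float = 100.0
    mz_max: float = 1200.0


class MassDetectionParams(_Section):
    noise_level: float = 600.0


class ChromatogramParams(_Section):
    min_span: float = 0.01
    min_height: float = 5.0e3
    mz_tol_abs: float = 0.01
    mz_tol_ppm: float = 5.0


class PeakFilterParams(_Section):
    rt_min: float = 0.01
    rt_max: float = 12.01


class DeconvolutionParams(_Section):
    baseline: float = 9.0e3
    min_peak_height: float = 1.0e4
    duration_min: float = 0.0
    duration_max: float = 2.0


class IsotopeGrouperParams(_Section):
    mz_tol_abs: float = 0.01
    mz_tol_ppm: float = 5.0
    rt_tol: float = 0.05
    monotonic: bool = True
    max_charge: int = 1


class AlignerParams(_Section):
    mz_tol_abs: float = 0.01
    mz_tol_ppm: float = 5.0
    mz_weight: float = 10.0
    rt_tol: float = 0.05
    rt_weight: float = 10.0
    require_same_charge: bool = True


class CurationParams(_Section):
    blank_rule: str = "any"        # any | all blank replicates
    abundance: str = "height"


class AttributionParams(_Section):
    reference_source: str = "qc"   # qc pools when present, else replicate union
    top_k: int = 3


class OrdinationParams(_Section):
    enabled: bool = True
    nmds_dims: int = 2
    nmds_starts: int = 20
    pca_components: int = 2
    ward_clusters: int = 2


class PipelineConfig(_Section):
    """Full pipeline configuration; section defaults are the reference
    protocol's printed processing parameters."""

    crop: CropParams = Field(default_factory=CropParams)
    mass_detection: MassDetectionParams = Field(default_factory=MassDetectionParams)
    chromatogram: ChromatogramParams = Field(default_factory=ChromatogramParams)
    peak_filter: PeakFilterParams = Field(default_factory=PeakFilterParams)
    deconvolution: DeconvolutionParams = Field(default_factory=DeconvolutionParams)
    isotope_grouper: IsotopeGrouperParams = Field(default_factory=IsotopeGrouperParams)
    aligner: AlignerParams = Field(default_factory=AlignerParams)
    curation: CurationParams = Field(default_factory=CurationParams)
    attribution: AttributionParams = Field(default_factory=AttributionParams)
    ordination: OrdinationParams = Field(default_factory=OrdinationParams)
    simulate: SimConfig | None = None
    manifest: str | None = None
    outdir: str = "residomics_out"
    seed: int = 0

    def feature_params(self) -> FeatureParams:
        return FeatureParams(
            scan_range=(self.crop.scan_min, self.crop.scan_max),
            rt_range=(self.crop.rt_min, self.crop.rt_max),
            mz_range=(self.crop.mz_min, self.crop.mz_max),
            noise_level=self.mass_detection.noise_level,
            chrom_min_span=self.chromatogram.min_span,
            chrom_min_height=self.chromatogram.min_height,
            chrom_mz_tol=Tolerance(self.chromatogram.mz_tol_abs,
                                   self.chromatogram.mz_tol_ppm),
            baseline=self.deconvolution.baseline,
            min_peak_height=self.deconvolution.min_peak_height,
            duration_range=(self.deconvolution.duration_min,
                            self.deconvolution.duration_max),
            rt_keep_window=(self.peak_filter.rt_min, self.peak_filter.rt_max),
            iso_mz_tol=Tolerance(self.isotope_grouper.mz_tol_abs,
                                 self.isotope_grouper.mz_tol_ppm),
            iso_rt_tol=self.isotope_grouper.rt_tol,
            iso_max_charge=self.isotope_grouper.max_charge,
            iso_monotonic=self.isotope_grouper.monotonic,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = json.loads(config.model_dump_json(exclude_none=True))
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


#: The printed protocol value behind each processing parameter, cited in
#: deviation reports.
_PROTOCOL_CITATIONS = {
    "mass_detection.noise_level": "noise level of 6.0E2",
    "chromatogram.min_span": "minimum time span 0.01 min",
    "chromatogram.min_height": "minimum height 5.0E3",
    "deconvolution.baseline": "baseline level of 9.0E3",
    "deconvolution.min_peak_height": "minimum peak height of 1.0E4",
}


@dataclass(frozen=True)
class Deviation:
    parameter: str
    value: object
    default: object
    citation: str = ""

    def __str__(self) -> str:
        s = f"{self.parameter} = {self.value} (protocol default {self.default}"
        if self.citation:
            s += f', "{self.citation}"'
        return s + ")"


def validate_config(config: PipelineConfig) -> list[Deviation]:
    """List every processing parameter differing from the protocol default."""
    defaults = PipelineConfig()
    out: list[Deviation] = []
    sections = ("crop", "mass_detection", "chromatogram", "peak_filter",
                "deconvolution", "isotope_grouper", "aligner")
    for sec in sections:
        cur, ref = getattr(config, sec), getattr(defaults, sec)
        for name in type(cur).model_fields:
            v, d = getattr(cur, name), getattr(ref, name)
            if v != d:
                key = f"{sec}.{name}"
                out.append(Deviation(key, v, d, _PROTOCOL_CITATIONS.get(key, "")))
    return out


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineResult:
    matrix: AlignedMatrix
    curated: AlignedMatrix
    compound_lists: dict[str, CompoundList]
    references: dict[str, CompoundList]
    reports: dict[str, AttributionReport]
    nmds: ordn.Ordination | None
    pca: ordn.Ordination | None
    counts: pd.DataFrame | None
    log: list[dict] = field(default_factory=list)


def reference_lists(
    matrix: AlignedMatrix, source: str = "qc"
) -> dict[str, CompoundList]:
    """Per-species reference compound lists from an aligned matrix.

    ``source="qc"`` prefers QC-pool columns for each species, falling back
    to the union of that species' replicate reference runs; ``"replicates"``
    always uses the replicate union.
    """
    cm = matrix.col_meta
    species = sorted({s for s in cm["species"] if s})
    out = {}
    for sp in species:
        cols = []
        if source == "qc":
            cols = list(cm.index[(cm["role"] == "qc") & (cm["species"] == sp)])
        if not cols:
            cols = list(cm.index[(cm["role"] == "species_ref") & (cm["species"] == sp)])
        if not cols:
            continue
        sub = matrix.abundance[cols]
        members = sub.max(axis=1)[sub.notna().any(axis=1)]
        out[sp] = CompoundList(sample=sp, members=members, token=matrix.token)
    return out


def run_study(
    runs: Mapping[str, CentroidRun], config: PipelineConfig
) -> PipelineResult:
    """Execute the in-memory pipeline on a set of runs."""
    stages: list[dict] = []

    def record(stage: str, **counts):
        entry = {"stage": stage, **counts}
        stages.append(entry)
        log.info("stage %s: %s", stage, counts)

    fparams = config.feature_params()
    feats = {}
    for rid in sorted(runs):
        try:
            all_feats = extract_features(runs[rid], fparams)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("extract_features", f"run {rid}: {exc}") from exc
        feats[rid] = representatives(all_feats)
    record("extract_features", runs=len(runs),
           features=sum(map(len, feats.values())))

    run_meta = {
        rid: {"sample": r.metadata.sample, "role": r.metadata.role,
              "solvent": r.metadata.solvent, "species": r.metadata.species}
        for rid, r in runs.items()
    }
    al = config.aligner
    matrix = join_align(feats, run_meta,
                        mz_tol=Tolerance(al.mz_tol_abs, al.mz_tol_ppm),
                        rt_tol=al.rt_tol, mz_weight=al.mz_weight,
                        rt_weight=al.rt_weight,
                        require_same_charge=al.require_same_charge)
    record("join_align", rows=matrix.n_rows,
           cells=int(matrix.abundance.notna().sum().sum()))

    curated = remove_blank_shared(matrix, rule=config.curation.blank_rule)
    record("remove_blank_shared", rows_in=matrix.n_rows, rows_out=curated.n_rows)

    cm = curated.col_meta
    target_samples = sorted(set(cm.loc[cm["role"] == "ancient", "sample"]))
    compound_lists = {s: merge_extracts(curated, s) for s in target_samples}
    record("merge_extracts", samples=len(compound_lists),
           sizes={s: len(cl) for s, cl in compound_lists.items()})

    references = reference_lists(curated, source=config.attribution.reference_source)
    reports = {s: venn_counts(cl, references)
               for s, cl in compound_lists.items()}
    record("attribution", targets=len(reports),
           rankings={s: r.ranking[:config.attribution.top_k]
                     for s, r in reports.items()})

    nmds_ord = pca_ord = counts = None
    all_lists = {**references, **compound_lists}
    if config.ordination.enabled and len(all_lists) > config.ordination.nmds_dims:
        dist = ordn.jaccard_distances(all_lists)
        nmds_ord = ordn.nmds(dist, k=config.ordination.nmds_dims,
                             n_starts=config.ordination.nmds_starts,
                             seed=config.seed)
        if 1 <= config.ordination.ward_clusters <= dist.shape[0]:
            nmds_ord.clusters = ordn.ward_cluster(
                dist, n_clusters=config.ordination.ward_clusters)
    if config.ordination.enabled and curated.n_rows and curated.abundance.shape[1] > 1:
        pca_ord = ordn.pareto_pca(curated, k=config.ordination.pca_components)
        counts = ordn.feature_count_summary(curated, group_by="solvent")
    record("ordination",
           nmds_stress=None if nmds_ord is None else round(nmds_ord.stress, 6))

    return PipelineResult(matrix=matrix, curated=curated,
                          compound_lists=compound_lists, references=references,
                          reports=reports, nmds=nmds_ord, pca=pca_ord,
                          counts=counts, log=stages)


def _load_manifest_runs(config: PipelineConfig) -> dict[str, CentroidRun]:
    from .io import RunMetadata

    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise StageError("load_runs", f"manifest file not found: {manifest_path}")
    mf = pd.read_csv(manifest_path, keep_default_na=False)
    runs = {}
    for rec in mf.itertuples():
        p = manifest_path.parent / rec.path
        if not p.exists():
            raise StageError("load_runs", f"run file not found: {p}")
        meta = RunMetadata(run_id=rec.run_id, sample=str(rec.sample),
                           role=str(rec.role), solvent=str(rec.solvent),
                           species=str(rec.species),
                           replicate=int(rec.replicate or 0))
        if p.suffix.lower() == ".mzml":
            run = read_mzml(p, metadata=meta)
        else:
            run = read_scan_csv(p)
            run.metadata = meta
        runs[rec.run_id] = run
    return runs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured pipeline and write the output bundle to
    ``config.outdir``; on stage failure a FAILED marker naming the stage
    is left in the output directory and the error re-raised."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        input_hashes = {}
        if config.manifest:
            runs = _load_manifest_runs(config)
            mp = Path(config.manifest)
            input_hashes[str(mp)] = hashlib.sha256(mp.read_bytes()).hexdigest()
        elif config.simulate is not None:
            bundle = make_study(config.simulate)
            runs = bundle.runs
        else:
            raise StageError("load_runs", "config needs either manifest or simulate")

        result = run_study(runs, config)

        result.curated.to_csv(outdir / "matrix.csv")
        for s, cl in sorted(result.compound_lists.items()):
            cl.to_csv(outdir / f"compounds_{s}.csv")
        for s, rep in sorted(result.reports.items()):
            rep.to_tsv(outdir / f"attribution_{s}.tsv")
            rep.to_json(outdir / f"attribution_{s}.json")
        if result.nmds is not None:
            result.nmds.coords.to_csv(outdir / "nmds_coords.csv")
        if result.pca is not None:
            result.pca.coords.to_csv(outdir / "pca_scores.csv")
        if result.counts is not None:
            result.counts.to_csv(outdir / "feature_counts.csv", index=False)
        save_config(config, outdir / "config_snapshot.yaml")
        (outdir / "input_hashes.json").write_text(
            json.dumps(input_hashes, indent=1, sort_keys=True))
        with (outdir / "log.jsonl").open("w") as fh:
            for entry in result.log:
                fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
        (outdir / "COMPLETE").write_text("ok\n")
        return result
    except StageError as err:
        failed_marker.write_text(f"{err.stage}\n{err}\n")
        raise
    except Exception as err:
        failed_marker.write_text(f"unknown\n{err}\n")
        raise
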