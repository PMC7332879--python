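"""Synthetic LC-MS study generator with known ground truth.

Emulates the experimental design the pipeline targets: reference pipes
smoked with 8 species, sequentially extracted with three solvents
(TA/APW/MTBE) in replicate; blank pipes contributing background features
to every run; QC pools per species x solvent; and "ancient" residue
samples that mix species signatures, lose compounds to degradation
(dropout), and gain environmental contaminants.

Compound m/z values are drawn without replacement from a coarse grid
(default 0.1 Th spacing, with sub-grid offsets), keeping distinct
compounds separated by more than twice the processing tolerances so that
ground-truth recovery is exact under moderate noise.  Each compound
elutes as a Gaussian in time; centroid m/z is perturbed per scan at the
ppm scale; intensities are log-normal in arbitrary detector counts with
defaults that clear the deconvolution minimum (1.0e4).

Randomness uses the counter-based Philox generator with per-run
substreams keyed by (seed, crc32(run id)), so any single run is
reproducible in isolation and output is byte-identical under a fixed
seed.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .align import AlignedMatrix
from .io import CentroidRun, CentroidScan, RunMetadata, write_mzml, write_scan_csv

__all__ = [
    "SimConfig",
    "SignatureSet",
    "StudyBundle",
    "make_signatures",
    "simulate_run",
    "make_manifest",
    "make_study",
    "write_study",
    "matrix_from_truth",
    "truth_sample_sets",
]

DEFAULT_SPECIES = ("AUV", "CSE", "NAT", "NQU", "NRU", "NTA", "RGL", "TBR")


class SimConfig(BaseModel):
    """Study-design and noise parameters of the generator.

    Defaults reproduce the reference design: 8 species x 3 solvents x 5
    replicates plus blanks, QC pools and one two-species ancient mixture;
    instrument-like noise (5 ppm m/z error, 0.02 min RT jitter, log-normal
    intensities) and a 100-1200 Th scan range sampled every 0.66 s over a
    12.5 min gradient.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    species: tuple[str, ...] = DEFAULT_SPECIES
    compounds_per_species: int = 60
    shared_fraction: float = Field(0.1, ge=0.0, le=1.0)
    solvents: tuple[str, ...] = ("TA", "APW", "MTBE")
    replicates: int = 5
    include_blank: bool = True
    blank_compounds: int = 30
    contaminant_compounds: int = 20
    mixtures: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {"PIPE_A": {"NQU": 0.5, "RGL": 0.5}})
    dropout: float = Field(0.3, ge=0.0, le=1.0)
    mz_error_ppm: float = Field(5.0, ge=0.0)
    rt_jitter_sd: float = Field(0.02, ge=0.0)
    intensity_sd: float = Field(0.3, ge=0.0)
    scan_interval_s: float = 0.66
    rt_min: float = 0.01
    rt_max: float = 12.50
    max_scans: int = 1130
    compound_rt_range: tuple[float, float] = (0.5, 12.0)
    peak_width_sd: float = 0.05
    noise_points_per_scan: int = 2
    noise_max: float = 590.0
    abundance_log10_mean: float = 5.2
    abundance_log10_sd: float = 0.3
    mz_min: float = 105.0
    mz_max: float = 1195.0
    mz_grid_step: float = 0.1
    plant_isotopes: bool = False
    seed: int = 0
    #: PRNG algorithm; fixed so seeds reproduce across platforms.
    prng: str = "philox4x64"


@dataclass
class SignatureSet:
    """Per-species compound signatures plus shared/blank/contaminant ledgers.

    ``compounds`` has one row per distinct compound (id, true m/z, RT,
    mean log10 abundance, solvent affinity, provenance kind, species
    membership); ``by_species`` maps each species code to its compound-id
    set (the signature); ``shared_ledger`` maps each compound id to the
    set of species carrying it.
    """

    compounds: pd.DataFrame
    by_species: dict[str, frozenset[str]]
    shared_ledger: dict[str, frozenset[str]]

    def blank_ids(self) -> frozenset[str]:
        return frozenset(self.compounds.index[self.compounds["kind"] == "blank"])

    def contaminant_ids(self) -> frozenset[str]:
        return frozenset(self.compounds.index[self.compounds["kind"] == "contaminant"])


def _rng(seed: int, run_id: str | None = None) -> np.random.Generator:
    sub = zlib.crc32(run_id.encode()) if run_id is not None else 0
    key = np.array([seed & 0xFFFFFFFF, sub], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def make_signatures(config: SimConfig) -> SignatureSet:
    """Build species signatures with exact pairwise overlap.

    Each unordered species pair shares ``round(shared_fraction * n)``
    compounds dedicated to that pair; the rest of each signature is
    unique, so every signature has exactly ``compounds_per_species``
    members.  Rejects infeasible fractions.
    """
    sp = list(config.species)
    n = config.compounds_per_species
    if config.shared_fraction > 1.0:
        raise ValueError("shared_fraction must be <= 1")
    if config.shared_fraction > 0 and len(sp) < 2:
        raise ValueError("need >= 2 species for a positive shared fraction")
    if config.shared_fraction == 1.0 and len(sp) > 1:
        k_shared, n_unique = 0, 0  # handled below: all species identical
    else:
        k_shared = round(config.shared_fraction * n)
        n_unique = n - k_shared * (len(sp) - 1)
        if n_unique < 0:
            raise ValueError(
                f"infeasible shared fraction: {k_shared} shared per pair x "
                f"{len(sp) - 1} partners exceeds signature size {n}")

    rng = _rng(config.seed)
    records: list[dict] = []
    if config.shared_fraction == 1.0 and len(sp) > 1:
        for i in range(n):
            records.append({"id": f"S_ALL_{i:04d}", "species": tuple(sp)})
    else:
        for a, b in combinations(sp, 2):
            for i in range(k_shared):
                records.append({"id": f"S_{a}_{b}_{i:04d}", "species": (a, b)})
        for s in sp:
            for i in range(n_unique):
                records.append({"id": f"U_{s}_{i:04d}", "species": (s,)})
    n_blank = config.blank_compounds if config.include_blank else 0
    for i in range(n_blank):
        records.append({"id": f"BL_{i:04d}", "species": ()})
    for i in range(config.contaminant_compounds):
        records.append({"id": f"CT_{i:04d}", "species": ()})

    total = len(records)
    grid = np.arange(config.mz_min, config.mz_max, config.mz_grid_step)
    if total > grid.size:
        raise ValueError("compound universe exceeds the m/z grid; widen the grid")
    slots = rng.choice(grid.size, size=total, replace=False)
    offsets = rng.uniform(-0.02, 0.02, size=total)
    mzs = grid[slots] + offsets
    rts = rng.uniform(*config.compound_rt_range, size=total)
    logab = rng.normal(config.abundance_log10_mean, config.abundance_log10_sd,
                       size=total)
    n_solv = len(config.solvents)
    sizes = rng.choice(np.arange(1, n_solv + 1), size=total,
                       p=_affinity_size_probs(n_solv))

    rows = []
    for i, rec in enumerate(records):
        aff = tuple(sorted(rng.choice(config.solvents, size=sizes[i], replace=False)))
        cid = rec["id"]
        if cid.startswith("BL_"):
            kind = "blank"
        elif cid.startswith("CT_"):
            kind = "contaminant"
        else:
            kind = "species"
        rows.append({
            "id": cid, "mz": float(mzs[i]), "rt": float(rts[i]),
            "log10_abundance": float(logab[i]), "affinity": aff,
            "kind": kind, "species": rec["species"],
        })
    compounds = pd.DataFrame(rows).set_index("id")
    by_species = {
        s: frozenset(compounds.index[[s in tup for tup in compounds["species"]]])
        for s in sp
    }
    shared_ledger = {
        cid: frozenset(tup)
        for cid, tup in compounds["species"].items() if len(tup) > 1
    }
    return SignatureSet(compounds=compounds, by_species=by_species,
                        shared_ledger=shared_ledger)


def _affinity_size_probs(n_solv: int) -> np.ndarray:
    # most compounds extract in one or two solvents, some in all
    base = {1: [1.0], 2: [0.4, 0.6], 3: [0.3, 0.4, 0.3]}
    p = base.get(n_solv, [1.0 / n_solv] * n_solv)
    return np.asarray(p) / np.sum(p)


def _scan_times(config: SimConfig) -> np.ndarray:
    step = config.scan_interval_s / 60.0
    n = min(int(math.floor((config.rt_max - config.rt_min) / step)) + 1,
            config.max_scans)
    return config.rt_min + np.arange(n) * step


def simulate_run(
    run_id: str,
    mixture: Mapping[str, float] | None,
    solvent: str,
    signatures: SignatureSet,
    config: SimConfig,
    metadata: RunMetadata | None = None,
    dropout: float = 0.0,
    include_contaminants: bool = False,
) -> tuple[CentroidRun, pd.DataFrame]:
    """Simulate one centroided run and its ground-truth ledger.

    ``mixture`` maps species codes to non-negative weights (relative
    abundance scale); ``None`` or an empty mixture simulates a blank pipe
    (background compounds only, which are present in *every* run).
    Dropout keeps ``ceil((1 - dropout) * n)`` of the eligible mixture
    compounds.  The truth ledger has one row per planted compound with its
    true m/z, realized apex RT and height, and provenance class (species
    code(s), "blank", or "contaminant").
    """
    rng = _rng(config.seed, run_id)
    comp = signatures.compounds
    in_solvent = comp["affinity"].map(lambda aff: solvent in aff)

    planted: list[dict] = []
    if mixture:
        if all(w == 0 for w in mixture.values()):
            raise ValueError("non-blank mixture weights must not all be zero")
        if any(w < 0 for w in mixture.values()):
            raise ValueError("mixture weights must be >= 0")
        weights: dict[str, float] = {}
        prov: dict[str, str] = {}
        for sp, w in sorted(mixture.items()):
            if w <= 0:
                continue
            for cid in sorted(signatures.by_species[sp]):
                if not in_solvent[cid]:
                    continue
                if cid not in weights or w > weights[cid]:
                    weights[cid] = w
                prov[cid] = "+".join(
                    sorted((set(prov.get(cid, "").split("+")) | {sp}) - {""}))
        eligible = sorted(weights)
        n_keep = math.ceil((1.0 - dropout) * len(eligible))
        keep_idx = sorted(rng.choice(len(eligible), size=n_keep, replace=False))
        for i in keep_idx:
            cid = eligible[i]
            planted.append({"id": cid, "provenance": prov[cid],
                            "weight": weights[cid]})
    if include_contaminants:
        for cid in sorted(signatures.contaminant_ids()):
            if in_solvent[cid]:
                planted.append({"id": cid, "provenance": "contaminant",
                                "weight": 1.0})
    for cid in sorted(signatures.blank_ids()):
        if in_solvent[cid]:
            planted.append({"id": cid, "provenance": "blank", "weight": 1.0})

    scan_rts = _scan_times(config)
    all_scan: list[np.ndarray] = []
    all_mz: list[np.ndarray] = []
    all_int: list[np.ndarray] = []
    truth_rows = []
    pw = config.peak_width_sd
    for rec in planted:
        row = comp.loc[rec["id"]]
        apex_rt = row.rt + rng.normal(0.0, config.rt_jitter_sd)
        height = 10.0 ** (row.log10_abundance
                          + rng.normal(0.0, config.intensity_sd)) * rec["weight"]
        lo = np.searchsorted(scan_rts, apex_rt - 4 * pw)
        hi = np.searchsorted(scan_rts, apex_rt + 4 * pw)
        idx = np.arange(lo, hi)
        if idx.size == 0:
            continue
        inten = height * np.exp(-0.5 * ((scan_rts[idx] - apex_rt) / pw) ** 2)
        keep = inten >= 1.0
        idx, inten = idx[keep], inten[keep]
        if idx.size == 0:
            continue
        mz = row.mz * (1.0 + rng.normal(0.0, config.mz_error_ppm, idx.size) / 1e6)
        all_scan.append(idx)
        all_mz.append(mz)
        all_int.append(inten)
        if config.plant_isotopes:
            # approximate A+1 isotopologue from a CHNO carbon-count heuristic
            ratio = 0.0107 * max(row.mz / 18.0, 1.0)
            iso_mz = (row.mz + 1.003355) * (
                1.0 + rng.normal(0.0, config.mz_error_ppm, idx.size) / 1e6)
            all_scan.append(idx.copy())
            all_mz.append(iso_mz)
            all_int.append(inten * min(ratio, 0.95))
        truth_rows.append({
            "compound_id": rec["id"], "mz": float(row.mz),
            "rt": float(apex_rt), "height": float(height),
            "provenance": rec["provenance"], "weight": rec["weight"],
        })

    n_noise = config.noise_points_per_scan * scan_rts.size
    if n_noise:
        noise_scan = np.repeat(np.arange(scan_rts.size), config.noise_points_per_scan)
        all_scan.append(noise_scan)
        all_mz.append(rng.uniform(100.0, 1200.0, n_noise))
        all_int.append(rng.uniform(1.0, config.noise_max, n_noise))

    scans = _assemble_scans(scan_rts, all_scan, all_mz, all_int)
    if metadata is None:
        metadata = RunMetadata(run_id=run_id, solvent=solvent,
                               role="blank" if not mixture else "species_ref")
    run = CentroidRun(metadata=metadata, scans=scans)
    truth = pd.DataFrame(truth_rows,
                         columns=["compound_id", "mz", "rt", "height",
                                  "provenance", "weight"])
    return run, truth


def _assemble_scans(scan_rts, all_scan, all_mz, all_int) -> list[CentroidScan]:
    if not all_scan:
        return [CentroidScan(i + 1, float(rt), np.empty(0), np.empty(0))
                for i, rt in enumerate(scan_rts)]
    scan_idx = np.concatenate(all_scan)
    mz = np.concatenate(all_mz)
    inten = np.concatenate(all_int)
    order = np.lexsort((mz, scan_idx))
    scan_idx, mz, inten = scan_idx[order], mz[order], inten[order]
    # enforce strictly increasing m/z within a scan (exact float collisions)
    dup = (np.diff(scan_idx) == 0) & (np.diff(mz) <= 0)
    while dup.any():
        mz[1:][dup] = mz[:-1][dup] + 1e-9
        order = np.lexsort((mz, scan_idx))
        scan_idx, mz, inten = scan_idx[order], mz[order], inten[order]
        dup = (np.diff(scan_idx) == 0) & (np.diff(mz) <= 0)
    bounds = np.searchsorted(scan_idx, np.arange(scan_rts.size + 1))
    scans = []
    for i, rt in enumerate(scan_rts):
        seg = slice(bounds[i], bounds[i + 1])
        scans.append(CentroidScan(i + 1, float(rt), mz[seg], inten[seg]))
    return scans


# --------------------------------------------------------------- manifest

def make_manifest(config: SimConfig, roles: Iterable[str] | None = None) -> pd.DataFrame:
    """Enumerate every run of the study design.

    Columns: run_id, sample, role, solvent, species, replicate.  QC pools
    cover every species (and the blank, when present) x solvent — with 3
    solvents and 8 species + blank that is 27 QC runs.  ``roles`` limits
    the manifest to a subset of {species_ref, blank, qc, ancient}.
    """
    rows = []
    for sp in config.species:
        for solv in config.solvents:
            for rep in range(1, config.replicates + 1):
                rows.append({"run_id": f"{sp}_{solv}_r{rep}",
                             "sample": f"{sp}_r{rep}", "role": "species_ref",
                             "solvent": solv, "species": sp, "replicate": rep})
    if config.include_blank:
        for solv in config.solvents:
            for rep in range(1, config.replicates + 1):
                rows.append({"run_id": f"BLANK_{solv}_r{rep}",
                             "sample": f"BLANK_r{rep}", "role": "blank",
                             "solvent": solv, "species": "", "replicate": rep})
    qc_species = list(config.species) + (["BLANK"] if config.include_blank else [])
    for sp in qc_species:
        for solv in config.solvents:
            rows.append({"run_id": f"QC_{sp}_{solv}", "sample": f"QC_{sp}",
                         "role": "qc", "solvent": solv,
                         "species": sp if sp != "BLANK" else "", "replicate": 0})
    for sample_id in sorted(config.mixtures):
        for solv in config.solvents:
            rows.append({"run_id": f"{sample_id}_{solv}", "sample": sample_id,
                         "role": "ancient", "solvent": solv, "species": "",
                         "replicate": 0})
    df = pd.DataFrame(rows)
    if roles is not None:
        df = df[df["role"].isin(set(roles))].reset_index(drop=True)
    return df


@dataclass
class StudyBundle:
    """A simulated study: config, run manifest, runs, and ground truth."""

    config: SimConfig
    manifest: pd.DataFrame
    signatures: SignatureSet
    runs: dict[str, CentroidRun]
    truth: dict[str, pd.DataFrame]  # run_id -> planted-compound ledger


def make_study(config: SimConfig, roles: Iterable[str] | None = None) -> StudyBundle:
    """Simulate the full study (or the roles subset) with ground truth."""
    signatures = make_signatures(config)
    manifest = make_manifest(config, roles=roles)
    runs: dict[str, CentroidRun] = {}
    truth: dict[str, pd.DataFrame] = {}
    for rec in manifest.itertuples():
        role = rec.role
        if role == "blank" or (role == "qc" and not rec.species):
            mixture = None
            dropout, contaminants = 0.0, False
        elif role in ("species_ref", "qc"):
            mixture = {rec.species: 1.0}
            dropout, contaminants = 0.0, False
        else:  # ancient
            mixture = config.mixtures[rec.sample]
            dropout, contaminants = config.dropout, True
        meta = RunMetadata(run_id=rec.run_id, sample=rec.sample, role=role,
                           solvent=rec.solvent, species=rec.species,
                           replicate=rec.replicate)
        run, t = simulate_run(rec.run_id, mixture, rec.solvent, signatures,
                              config, metadata=meta, dropout=dropout,
                              include_contaminants=contaminants)
        runs[rec.run_id] = run
        truth[rec.run_id] = t
    return StudyBundle(config=config, manifest=manifest, signatures=signatures,
                       runs=runs, truth=truth)


def write_study(bundle: StudyBundle, outdir: str | Path, fmt: str = "csv") -> None:
    """Write runs (scan CSV or mzML), the manifest, and the truth ledger."""
    outdir = Path(outdir)
    (outdir / "runs").mkdir(parents=True, exist_ok=True)
    manifest = bundle.manifest.copy()
    paths = []
    for rec in manifest.itertuples():
        run = bundle.runs[rec.run_id]
        if fmt == "csv":
            p = outdir / "runs" / f"{rec.run_id}.csv"
            write_scan_csv(run, p)
        elif fmt == "mzml":
            p = outdir / "runs" / f"{rec.run_id}.mzML"
            write_mzml(run, p)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths.append(str(p.relative_to(outdir)))
    manifest["path"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    truth = {
        "config": json.loads(bundle.config.model_dump_json()),
        "per_run": {rid: df.to_dict(orient="records")
                    for rid, df in sorted(bundle.truth.items())},
        "compounds": {
            cid: {"mz": float(r.mz), "rt": float(r.rt), "kind": r.kind,
                  "species": list(r.species), "affinity": list(r.affinity)}
            for cid, r in bundle.signatures.compounds.iterrows()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


# ----------------------------------------------------- ground-truth views

def matrix_from_truth(bundle: StudyBundle) -> AlignedMatrix:
    """An idealized aligned matrix built directly from the truth ledger
    (row per compound id, cell = planted apex height) — the oracle input
    for curation and attribution logic, bypassing feature extraction."""
    run_ids = sorted(bundle.runs)
    all_ids = sorted({cid for rid in run_ids
                      for cid in bundle.truth[rid]["compound_id"]})
    abundance = pd.DataFrame(np.nan, index=pd.Index(all_ids, name="row_id"),
                             columns=run_ids)
    for rid in run_ids:
        t = bundle.truth[rid]
        abundance.loc[t["compound_id"].to_numpy(), rid] = t["height"].to_numpy()
    comp = bundle.signatures.compounds
    row_meta = pd.DataFrame({
        "mz": [comp.loc[cid, "mz"] for cid in all_ids],
        "rt": [comp.loc[cid, "rt"] for cid in all_ids],
    }, index=abundance.index)
    mf = bundle.manifest.set_index("run_id")
    col_meta = pd.DataFrame(
        {k: [mf.loc[r, k] for r in run_ids]
         for k in ("sample", "role", "solvent", "species")},
        index=pd.Index(run_ids, name="run_id"),
    )
    return AlignedMatrix(abundance=abundance, row_meta=row_meta, col_meta=col_meta)


def truth_sample_sets(bundle: StudyBundle) -> dict[str, frozenset[str]]:
    """Per-sample planted compound-id sets (union over the sample's runs)."""
    out: dict[str, set[str]] = {}
    for rec in bundle.manifest.itertuples():
        out.setdefault(rec.sample, set()).update(
            bundle.truth[rec.run_id]["compound_id"])
    return {s: frozenset(v) for s, v in out.items()}
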