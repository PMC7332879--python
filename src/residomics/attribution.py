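"""Species attribution by compound-set intersection, plus biomarker
annotation with isobar discrimination.

The inferential core is deliberately simple presence/absence set algebra:
the artifact sample's compound list is intersected with each reference
species' list (all drawn from one aligned matrix, so row ids are exactly
comparable), and species are ranked by shared-compound count.  No minimum
count is imposed — the report is ranked evidence, not a use/no-use call.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem
from .align import AlignedMatrix, CompoundList
from .features import Tolerance

log = logging.getLogger(__name__)

__all__ = [
    "AttributionReport",
    "BiomarkerEntry",
    "Annotation",
    "venn_counts",
    "rank_species",
    "annotate_biomarkers",
    "load_biomarker_library",
    "fragment_cosine",
]


@dataclass
class AttributionReport:
    """Per-species exclusive and shared-with-target compound counts.

    ``table`` columns: species, exclusive (compounds in that reference and
    no other reference), shared (compounds common to the target and that
    reference).  ``ranking`` orders species by shared count descending,
    ties broken alphabetically and listed in ``ties``.
    """

    target: str
    table: pd.DataFrame
    ranking: list[str]
    ties: list[tuple[str, ...]] = field(default_factory=list)
    total_target: int = 0

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target": self.target,
            "total_target_compounds": self.total_target,
            "species": self.table.to_dict(orient="records"),
            "ranking": self.ranking,
            "ties": [list(t) for t in self.ties],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def venn_counts(
    target: CompoundList, references: Mapping[str, CompoundList]
) -> AttributionReport:
    """Venn-style intersection counts of a target against reference lists.

    All lists must come from the same aligned matrix (same token);
    ``exclusive(s)`` counts compounds in reference ``s`` and in no other
    reference, ``shared(s)`` counts compounds common to target and ``s``.
    """
    for name, ref in references.items():
        if ref.token != target.token:
            raise ValueError(
                f"compound lists are not comparable: reference {name!r} comes "
                "from a different aligned matrix than the target")
    t_ids = target.ids
    species = sorted(references)
    rows = []
    for s in species:
        others = frozenset().union(*(references[o].ids for o in species if o != s)) \
            if len(species) > 1 else frozenset()
        rows.append({
            "species": s,
            "exclusive": len(references[s].ids - others),
            "shared": len(references[s].ids & t_ids),
        })
    table = pd.DataFrame(rows, columns=["species", "exclusive", "shared"])
    ranked = sorted(rows, key=lambda r: (-r["shared"], r["species"]))
    ranking = [r["species"] for r in ranked]
    ties = []
    by_count: dict[int, list[str]] = {}
    for r in rows:
        by_count.setdefault(r["shared"], []).append(r["species"])
    for count, group in by_count.items():
        if len(group) > 1:
            ties.append(tuple(sorted(group)))
    return AttributionReport(target=target.sample, table=table, ranking=ranking,
                             ties=sorted(ties), total_target=len(t_ids))


def rank_species(report: AttributionReport, top_k: int | None = None) -> list[str]:
    """Top-k species by shared count; an all-zero report yields an empty
    ranking (with a warning) rather than an arbitrary order."""
    shared = dict(zip(report.table["species"], report.table["shared"]))
    if all(v == 0 for v in shared.values()):
        log.warning("rank_species: no reference shares any compound with %s",
                    report.target)
        return []
    ranking = [s for s in report.ranking if shared[s] > 0 or top_k is None]
    return ranking[:top_k] if top_k is not None else ranking


# ------------------------------------------------------------- biomarkers

@dataclass(frozen=True)
class BiomarkerEntry:
    """One library standard: identity, adduct, observed m/z and RT on the
    reference chromatographic method, optional pseudo-MS/MS fragment list."""

    name: str
    formula: chem.ElementFormula
    adduct: chem.AdductSpec
    observed_mz: float
    rt: float
    fragments: tuple[tuple[float, float], ...] = ()  # (mz, relative intensity)

    def __post_init__(self):
        if self.rt <= 0:
            raise ValueError("RT must be positive")
        theory = chem.adduct_mz(self.formula, self.adduct)
        if abs(self.observed_mz - theory) > 0.05:
            raise ValueError(
                f"{self.name}: observed m/z {self.observed_mz} deviates more than "
                f"0.05 Th from {self.adduct.name} theory {theory:.4f}")


def load_biomarker_library(path: str | Path | None = None) -> list[BiomarkerEntry]:
    """Load a biomarker library CSV; defaults to the bundled seven-standard
    smoke-plant library (nicotine, anabasine, cotinine, arbutin, caffeine,
    theobromine, theophylline)."""
    if path is None:
        ref = importlib.resources.files("residomics.data") / "biomarkers.csv"
        fh = ref.open()
    else:
        fh = open(path)
    with fh:
        rows = [r for r in fh if not r.startswith("#")]
    entries = []
    for rec in csv.DictReader(rows):
        frags = tuple(
            (float(p.split(":")[0]), float(p.split(":")[1]))
            for p in (rec.get("fragments") or "").split(";") if p.strip()
        )
        entries.append(BiomarkerEntry(
            name=rec["name"],
            formula=chem.ElementFormula.parse(rec["formula"]),
            adduct=chem.parse_adduct(rec["adduct"]),
            observed_mz=float(rec["observed_mz"]),
            rt=float(rec["rt_min"]),
            fragments=frags,
        ))
    return entries


def fragment_cosine(
    a: Sequence[tuple[float, float]],
    b: Sequence[tuple[float, float]],
    bin_width: float = 0.02,
) -> float:
    """Cosine similarity of two fragment lists over fixed m/z bins."""
    if not a or not b:
        return 0.0
    def vec(frags):
        d: dict[int, float] = {}
        for mz, inten in frags:
            d[int(round(mz / bin_width))] = d.get(int(round(mz / bin_width)), 0.0) + inten
        return d
    va, vb = vec(a), vec(b)
    dot = sum(va[k] * vb[k] for k in va.keys() & vb.keys())
    na = np.sqrt(sum(v * v for v in va.values()))
    nb = np.sqrt(sum(v * v for v in vb.values()))
    return float(dot / (na * nb)) if na and nb else 0.0


@dataclass(frozen=True)
class Annotation:
    """Annotation status of one aligned row: a unique call, an ambiguous
    isobar set (never silently resolved), or nothing."""

    row_id: int
    status: str  # "unique" | "ambiguous"
    names: tuple[str, ...]


def annotate_biomarkers(
    matrix: AlignedMatrix,
    library: Sequence[BiomarkerEntry],
    mz_tol: Tolerance = Tolerance(0.01, 5.0),
    rt_tol: float = 0.1,
    row_fragments: Mapping[int, Sequence[tuple[float, float]]] | None = None,
    fragment_threshold: float = 0.7,
) -> list[Annotation]:
    """Annotate matrix rows against a biomarker library.

    A row is annotated with every entry whose observed m/z and RT are both
    within tolerance.  Isobars (several entries within the m/z window) are
    discriminated by RT first; if several remain and fragment spectra are
    available for the row, a unique fragment-cosine winner (>= threshold)
    is called; otherwise the row is reported ambiguous with all candidate
    names.  The library RTs must come from the same chromatographic method
    as the data — that correspondence is the caller's responsibility.
    """
    annotations = []
    for row_id, row in matrix.row_meta.iterrows():
        mz_hits = [e for e in library
                   if abs(e.observed_mz - row.mz) <= mz_tol.window(row.mz)]
        hits = [e for e in mz_hits if abs(e.rt - row.rt) <= rt_tol]
        if not hits:
            continue
        if len(hits) == 1:
            annotations.append(Annotation(row_id, "unique", (hits[0].name,)))
            continue
        frags = (row_fragments or {}).get(row_id)
        if frags:
            scored = [(fragment_cosine(frags, e.fragments), e.name)
                      for e in hits if e.fragments]
            passing = sorted((s, n) for s, n in scored if s >= fragment_threshold)
            if len(passing) >= 1 and (len(passing) == 1
                                      or passing[-1][0] > passing[-2][0]):
                annotations.append(Annotation(row_id, "unique", (passing[-1][1],)))
                continue
        annotations.append(
            Annotation(row_id, "ambiguous", tuple(sorted(e.name for e in hits))))
    return annotations
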