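"""Protein-level SILAC enrichment for IP vs mock-IP experiments.

Heavy/light peptide intensity ratios from a SILAC co-immunoprecipitation are
aggregated per protein by the median (robust to single-peptide outliers);
enrichment is then a simple ratio threshold with ranking by ratio and summed
intensity, mirroring the usual ratio-versus-intensity scatter presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log2

from .errors import InputError


@dataclass(frozen=True)
class PeptideRecord:
    protein_id: str
    peptide_id: str
    heavy_intensity: float
    light_intensity: float


@dataclass(frozen=True)
class ProteinEnrichment:
    protein_id: str
    ratio: float
    log2_ratio: float
    summed_intensity: float
    n_peptides: int
    enriched: bool = False


@dataclass
class ProteinRatioResult:
    """Per-protein ratios plus bookkeeping on filtered records."""

    proteins: list[ProteinEnrichment]
    n_zero_filtered: int = 0
    n_proteins_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list)


def _median(values: list[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def protein_ratios(
    peptides: list[PeptideRecord], min_peptides: int = 1
) -> ProteinRatioResult:
    """Median peptide heavy/light ratio per protein.

    Records with non-positive heavy or light intensity are dropped (counted in
    ``n_zero_filtered``); proteins with fewer than ``min_peptides`` remaining
    peptides are excluded (counted and listed).
    """
    if min_peptides < 1:
        raise InputError("min_peptides must be >= 1")
    by_protein: dict[str, list[PeptideRecord]] = {}
    n_zero = 0
    for rec in peptides:
        if rec.heavy_intensity <= 0 or rec.light_intensity <= 0:
            n_zero += 1
            continue
        by_protein.setdefault(rec.protein_id, []).append(rec)

    proteins: list[ProteinEnrichment] = []
    excluded: list[str] = []
    for pid in sorted(by_protein):
        recs = by_protein[pid]
        if len(recs) < min_peptides:
            excluded.append(pid)
            continue
        ratios = [r.heavy_intensity / r.light_intensity for r in recs]
        ratio = _median(ratios)
        proteins.append(
            ProteinEnrichment(
                protein_id=pid,
                ratio=ratio,
                log2_ratio=log2(ratio),
                summed_intensity=sum(
                    r.heavy_intensity + r.light_intensity for r in recs
                ),
                n_peptides=len(recs),
            )
        )
    return ProteinRatioResult(
        proteins=proteins,
        n_zero_filtered=n_zero,
        n_proteins_excluded=len(excluded),
        excluded_ids=excluded,
    )


def classify_enriched(
    enrichments: list[ProteinEnrichment],
    ratio_threshold: float,
    intensity_floor: float = 0.0,
) -> list[ProteinEnrichment]:
    """Proteins above the ratio threshold (and intensity floor), ranked.

    Ranking is deterministic: descending ratio, then descending summed
    intensity, then protein id.
    """
    if ratio_threshold <= 0:
        raise InputError("ratio_threshold must be positive")
    hits = [
        replace(e, enriched=True)
        for e in enrichments
        if e.ratio >= ratio_threshold and e.summed_intensity >= intensity_floor
    ]
    hits.sort(key=lambda e: (-e.ratio, -e.summed_intensity, e.protein_id))
    return hits
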