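"""Variant catalog I/O and quality screening.

The quality screen mirrors the catalog filtering used for macaque
population variant data: drop variants with QUAL < 30, site depth
outside [10, 50], indels, and non-autosomal records.  Thresholds are
strict exclusion bounds, so QUAL exactly 30 and DP exactly 10 or 50 are
retained.  Each dropped record is attributed to exactly one reason with
fixed precedence (qual -> depth -> indel -> non-autosome) so that counts
are conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Optional, Sequence

import pysam

EFFECTS = ("missense", "lof", "synonymous", "noncoding")
FUNCTIONAL_EFFECTS = frozenset({"missense", "lof"})
CODING_EFFECTS = frozenset({"missense", "lof", "synonymous"})

#: Rhesus macaque autosome labels (20 autosomes).
MACAQUE_AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 21))

_NUCS = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when the VCF cannot be parsed; carries the record index."""


@dataclass(frozen=True)
class VariantRecord:
    """One catalog variant, one ALT allele per record.

    ``pos`` is 1-based.  ``effect`` is one of :data:`EFFECTS` or ``None``
    when the record carries no annotation.  ``damaging`` marks alleles
    predicted damaging upstream (ClinVar-pathogenic / PolyPhen2 /
    SnpEff-high); it is consumed as an input flag, never computed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    allele_freq: Optional[float] = None
    gene: Optional[str] = None
    effect: Optional[str] = None
    damaging: bool = False
    cadd: Optional[float] = None

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _NUCS
            and self.alt in _NUCS
        )

    @property
    def annotated(self) -> bool:
        return self.gene is not None and self.effect is not None


@dataclass
class QCSummary:
    """Bookkeeping for one pass of :func:`qc_filter`.

    ``n_input == n_retained + n_dropped_qual + n_dropped_depth +
    n_dropped_indel + n_dropped_nonautosome`` always holds: precedence
    assigns each dropped record a single reason.  ``snv_fraction`` is the
    percentage of SNVs among qual/depth survivors, at 1 decimal place.
    """

    n_input: int = 0
    n_dropped_qual: int = 0
    n_dropped_depth: int = 0
    n_dropped_indel: int = 0
    n_dropped_nonautosome: int = 0
    n_retained: int = 0
    n_snv_retained: int = 0
    n_indel_seen: int = 0

    @property
    def snv_fraction(self) -> Optional[float]:
        """SNV percentage among qual/depth survivors (1 d.p., half-up)."""
        denom = self.n_snv_retained + self.n_indel_seen
        if denom == 0:
            return None
        return round_percent(self.n_snv_retained, denom)

    def check_conservation(self) -> bool:
        dropped = (
            self.n_dropped_qual
            + self.n_dropped_depth
            + self.n_dropped_indel
            + self.n_dropped_nonautosome
        )
        return self.n_input == self.n_retained + dropped


def round_percent(numerator: float, denominator: float) -> float:
    """100*num/den rounded half-up to 1 decimal place."""
    if denominator == 0:
        raise ZeroDivisionError("cannot compute a percentage of zero")
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _allele_value(value, index: int):
    """Pick the per-ALT entry from a Number=A INFO value."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if index >= len(value):
            return None
        return value[index]
    return value if index == 0 else None


def read_catalog(vcf_path) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` from a VCF 4.x file.

    Multi-allelic sites are split into one record per ALT allele; the
    per-allele INFO keys (EFFECT, AF, DMG, CADD) are Number=A.  A record
    missing GENE/EFFECT is yielded un-annotated rather than dropped.
    Malformed input raises :class:`VcfParseError` naming the failing
    record index.
    """
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot open VCF {vcf_path!r}: {exc}") from exc
    with vf:
        it = iter(vf)
        i = 0
        while True:
            i += 1
            try:
                site = next(it)
            except StopIteration:
                return
            except (ValueError, OSError) as exc:
                raise VcfParseError(
                    f"malformed VCF record #{i} in {vcf_path!r}: {exc}"
                ) from exc
            info = site.info
            gene = info.get("GENE")
            depth = info.get("DP", 0) or 0
            qual = site.qual if site.qual is not None else 0.0
            alts = site.alts or ()
            for a_idx, alt in enumerate(alts):
                effect = _allele_value(info.get("EFFECT"), a_idx)
                af = _allele_value(info.get("AF"), a_idx)
                dmg = _allele_value(info.get("DMG"), a_idx)
                cadd = _allele_value(info.get("CADD"), a_idx)
                if effect is not None and effect not in EFFECTS:
                    raise VcfParseError(
                        f"record #{i}: unknown EFFECT {effect!r} "
                        f"(expected one of {EFFECTS})"
                    )
                yield VariantRecord(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=alt,
                    qual=float(qual),
                    depth=int(depth),
                    allele_freq=float(af) if af is not None else None,
                    gene=str(gene) if gene is not None else None,
                    effect=str(effect) if effect is not None else None,
                    damaging=bool(dmg),
                    cadd=float(cadd) if cadd is not None else None,
                )


def qc_filter(
    records: Iterable[VariantRecord],
    qual_min: float = 30.0,
    depth_min: int = 10,
    depth_max: int = 50,
    autosomes: frozenset = MACAQUE_AUTOSOMES,
) -> tuple[list[VariantRecord], QCSummary]:
    """Apply the quality screen; return retained records and counts.

    A record is retained iff qual >= qual_min, depth_min <= depth <=
    depth_max, it is a single-nucleotide substitution, and its chromosome
    is in ``autosomes``.  Drop reasons follow the fixed precedence
    qual -> depth -> indel -> non-autosome.
    """
    if not autosomes:
        raise ValueError("autosome set must be non-empty")
    summary = QCSummary()
    retained: list[VariantRecord] = []
    for rec in records:
        summary.n_input += 1
        if rec.qual < qual_min:
            summary.n_dropped_qual += 1
            continue
        if rec.depth < depth_min or rec.depth > depth_max:
            summary.n_dropped_depth += 1
            continue
        if not rec.is_snv:
            summary.n_dropped_indel += 1
            summary.n_indel_seen += 1
            continue
        summary.n_snv_retained += 1
        if rec.chrom not in autosomes:
            summary.n_dropped_nonautosome += 1
            continue
        summary.n_retained += 1
        retained.append(rec)
    return retained, summary


def summarize_qc(summary: QCSummary) -> str:
    """Render a QC summary as a small TSV report (counts exact,
    percentages at 1 d.p., ``NA`` when undefined)."""

    def pct(num: int, den: int) -> str:
        return "NA" if den == 0 else f"{round_percent(num, den):.1f}"

    sf = summary.snv_fraction
    rows = [
        ("n_input", summary.n_input, ""),
        ("n_dropped_qual", summary.n_dropped_qual, pct(summary.n_dropped_qual, summary.n_input)),
        ("n_dropped_depth", summary.n_dropped_depth, pct(summary.n_dropped_depth, summary.n_input)),
        ("n_dropped_indel", summary.n_dropped_indel, pct(summary.n_dropped_indel, summary.n_input)),
        ("n_dropped_nonautosome", summary.n_dropped_nonautosome, pct(summary.n_dropped_nonautosome, summary.n_input)),
        ("n_retained", summary.n_retained, pct(summary.n_retained, summary.n_input)),
        ("n_snv_retained", summary.n_snv_retained, ""),
        ("n_indel_seen", summary.n_indel_seen, ""),
        ("snv_fraction", "NA" if sf is None else f"{sf:.1f}", ""),
        ("conserved", str(summary.check_conservation()).lower(), ""),
    ]
    lines = ["metric\tvalue\tpercent_of_input"]
    lines.extend(f"{k}\t{v}\t{p}" for k, v, p in rows)
    return "\n".join(lines) + "\n"
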