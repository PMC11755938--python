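"""Cross-assembly coordinate liftover and disease-variant overlap.

Chain files (UCSC chain format) describe gapped alignments between a
source ("target" in chain-header parlance, the assembly lifted FROM) and
a destination ("query", the assembly lifted TO).  Point positions inside
an aligned block map by offset; positions falling in alignment gaps or
outside any chain are reported unmapped, never as errors.  Negative
destination strands are handled by coordinate reflection.

Downstream, predicted-damaging variants are lifted and intersected with
a disease-variant catalog (match = identical lifted chrom/pos AND
identical ref/alt alleles), per-set gene damage proportions are
tabulated, and damaging variants ranked by CADD score.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ChainParseError(ValueError):
    """Malformed chain file (bad header or block-size bookkeeping)."""


@dataclass(frozen=True)
class ChainBlock:
    """One gapless aligned block, absolute 0-based half-open intervals.

    ``dst_start`` is on the forward strand of the destination sequence
    when ``dst_strand`` is '+'; for '-' it is a position on the reversed
    sequence and is reflected at lookup time.
    """

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_size: int
    dst_strand: str
    dst_start: int
    score: int
    chain_id: int


@dataclass
class ChainIndex:
    """Blocks grouped by source chromosome, sorted by source start."""

    blocks: dict = field(default_factory=dict)  # chrom -> list[ChainBlock]
    _starts: dict = field(default_factory=dict, repr=False)

    def add(self, block: ChainBlock) -> None:
        self.blocks.setdefault(block.src_chrom, []).append(block)

    def finalize(self) -> None:
        for chrom, blist in self.blocks.items():
            blist.sort(key=lambda b: (b.src_start, -b.score))
            self._starts[chrom] = [b.src_start for b in blist]


def parse_chain(path) -> ChainIndex:
    """Parse a UCSC chain file into a point-queryable index.

    Validates that the cumulative block/gap arithmetic matches the
    declared interval ends; mismatches raise :class:`ChainParseError`
    naming the chain id.
    """
    index = ChainIndex()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n_chains = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise ChainParseError(f"expected 'chain' header, got {line!r}")
        parts = line.split()
        if len(parts) != 13:
            raise ChainParseError(f"bad chain header ({len(parts)} fields): {line!r}")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
        score, t_size, t_start, t_end = map(int, (score, t_size, t_start, t_end))
        q_size, q_start, q_end, chain_id = map(int, (q_size, q_start, q_end, chain_id))
        if t_strand != "+":
            raise ChainParseError(
                f"chain {chain_id}: source strand must be '+', got {t_strand!r}"
            )
        if q_strand not in "+-":
            raise ChainParseError(f"chain {chain_id}: bad strand {q_strand!r}")
        # block lines: size [dt dq]; last line is size only
        t_pos, q_pos = t_start, q_start
        done = False
        saw_block = False
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                if not saw_block:
                    continue
                break
            fields = row.split()
            if fields[0] == "chain":
                i -= 1
                break
            try:
                nums = [int(x) for x in fields]
            except ValueError as exc:
                raise ChainParseError(
                    f"chain {chain_id}: bad block line {row!r}"
                ) from exc
            if len(nums) not in (1, 3):
                raise ChainParseError(
                    f"chain {chain_id}: block line must have 1 or 3 fields: {row!r}"
                )
            size = nums[0]
            saw_block = True
            index.add(
                ChainBlock(
                    src_chrom=t_name,
                    src_start=t_pos,
                    src_end=t_pos + size,
                    dst_chrom=q_name,
                    dst_size=q_size,
                    dst_strand=q_strand,
                    dst_start=q_pos,
                    score=score,
                    chain_id=chain_id,
                )
            )
            if len(nums) == 3:
                dt, dq = nums[1], nums[2]
                t_pos += size + dt
                q_pos += size + dq
            else:
                t_pos += size
                q_pos += size
                done = True
                break
        if not saw_block or not done:
            raise ChainParseError(f"chain {chain_id}: truncated block list")
        if t_pos != t_end or q_pos != q_end:
            raise ChainParseError(
                f"chain {chain_id}: block arithmetic mismatch "
                f"(source reaches {t_pos}, declared end {t_end}; "
                f"dest reaches {q_pos}, declared end {q_end})"
            )
        n_chains += 1
    if n_chains == 0:
        raise ChainParseError(f"no chains found in {path!r}")
    index.finalize()
    return index


def lift_position(
    index: ChainIndex, chrom: str, pos_1based: int
) -> Optional[tuple[str, int, str]]:
    """Map a 1-based position; returns (chrom, pos_1based, strand) or None.

    Positions inside a gap or outside every chain are unmapped (None).
    When several chains cover a position the highest-score chain wins.
    """
    blist = index.blocks.get(chrom)
    if not blist:
        return None
    pos0 = pos_1based - 1
    starts = index._starts[chrom]
    j = bisect_right(starts, pos0)
    best: Optional[ChainBlock] = None
    for b in blist[:j][::-1]:
        if b.src_start <= pos0 < b.src_end:
            if best is None or b.score > best.score:
                best = b
        elif b.src_end <= pos0 and best is not None:
            break
    if best is None:
        return None
    offset = pos0 - best.src_start
    dst0 = best.dst_start + offset
    if best.dst_strand == "-":
        dst0 = best.dst_size - 1 - dst0
    return best.dst_chrom, dst0 + 1, best.dst_strand


def invert_chain(in_path, out_path) -> None:
    """Write the inverse chain (swap source and destination sides).

    Only '+'/'+' chains are invertible here; enough for round-trip
    checks on toy assembly maps.
    """
    out_lines = []
    with open(in_path) as fh:
        for ln in fh:
            s = ln.strip()
            if s.startswith("chain"):
                p = s.split()
                (_, score, t_name, t_size, t_strand, t_start, t_end,
                 q_name, q_size, q_strand, q_start, q_end, cid) = p
                if q_strand != "+":
                    raise ChainParseError(
                        "cannot invert a chain with '-' destination strand"
                    )
                out_lines.append(
                    f"chain {score} {q_name} {q_size} {q_strand} {q_start} "
                    f"{q_end} {t_name} {t_size} {t_strand} {t_start} {t_end} {cid}"
                )
            elif s:
                nums = s.split()
                if len(nums) == 3:
                    size, dt, dq = nums
                    out_lines.append(f"{size} {dq} {dt}")  # gaps swap sides
                else:
                    out_lines.append(s)
            else:
                out_lines.append("")
    with open(out_path, "w") as fh:
        fh.write("\n".join(out_lines) + "\n")


@dataclass(frozen=True)
class DamagingVariant:
    """A predicted-damaging catalog variant (flags consumed, not computed)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    clinvar_pathogenic: bool = False
    polyphen_damaging: bool = False
    snpeff_high: bool = False
    cadd: Optional[float] = None

    def __post_init__(self):
        if not (self.clinvar_pathogenic or self.polyphen_damaging or self.snpeff_high):
            raise ValueError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}: at least one "
                "damaging-source flag must be set"
            )


def read_damaging_table(path) -> list[DamagingVariant]:
    """TSV: chrom pos ref alt gene clinvar polyphen snpeff cadd."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        cadd = getattr(row, "cadd", None)
        out.append(
            DamagingVariant(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene=str(row.gene),
                clinvar_pathogenic=bool(row.clinvar),
                polyphen_damaging=bool(row.polyphen),
                snpeff_high=bool(row.snpeff),
                cadd=None if cadd is None or pd.isna(cadd) else float(cadd),
            )
        )
    return out


def read_disease_catalog(path) -> pd.DataFrame:
    """TSV: chrom pos ref alt disease (1-based positions, destination assembly)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def overlap_disease_variants(
    damaging: Iterable[DamagingVariant],
    index: ChainIndex,
    disease_catalog: pd.DataFrame,
    strand_aware_flip: bool = False,
) -> pd.DataFrame:
    """Lift damaging variants and intersect with the disease catalog.

    A match requires identical lifted (chrom, pos) and identical ref/alt
    alleles; with ``strand_aware_flip`` a variant lifted to the '-'
    strand has its alleles reverse-complemented before comparison.  Each
    (damaging variant, disease variant) pair is reported at most once.
    """
    lookup: dict[tuple, list] = {}
    for row in disease_catalog.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        lookup.setdefault(key, []).append(str(row.disease))
    rows = []
    seen = set()
    for dv in damaging:
        mapped = lift_position(index, dv.chrom, dv.pos)
        if mapped is None:
            continue
        chrom, pos, strand = mapped
        ref, alt = dv.ref, dv.alt
        if strand == "-" and strand_aware_flip:
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        for disease in lookup.get((chrom, pos, ref, alt), ()):
            pair = (dv.chrom, dv.pos, dv.ref, dv.alt, chrom, pos, disease)
            if pair in seen:
                continue
            seen.add(pair)
            rows.append(
                {
                    "src_chrom": dv.chrom,
                    "src_pos": dv.pos,
                    "ref": dv.ref,
                    "alt": dv.alt,
                    "gene": dv.gene,
                    "dst_chrom": chrom,
                    "dst_pos": pos,
                    "disease": disease,
                }
            )
    cols = ["src_chrom", "src_pos", "ref", "alt", "gene", "dst_chrom",
            "dst_pos", "disease"]
    return pd.DataFrame(rows, columns=cols)


def set_damage_report(
    gene_sets: Iterable, damaging: Iterable[DamagingVariant]
) -> pd.DataFrame:
    """Per-set proportion of genes carrying >= 1 predicted-damaging variant.

    Gene-level presence, not counts: duplicating variants changes
    nothing.  Proportions are percentages rounded half-up to 1 d.p.
    """
    from .qc import round_percent

    damaged_genes = {dv.gene for dv in damaging}
    rows = []
    for gs in gene_sets:
        n_genes = len(gs.members)
        n_with = len(set(gs.members) & damaged_genes)
        rows.append(
            {
                "set_name": gs.name,
                "n_genes_in_db": n_genes,
                "n_genes_with_damaging": n_with,
                "proportion_pct": round_percent(n_with, n_genes),
            }
        )
    return pd.DataFrame(rows)


_CHROM_RE = re.compile(r"^(?:chr)?(\d+|[XYM]|MT)$", re.IGNORECASE)


def _chrom_sort_key(chrom: str):
    m = _CHROM_RE.match(chrom)
    if m:
        tok = m.group(1)
        if tok.isdigit():
            return (0, int(tok), "")
        return (1, 0, tok.upper())
    return (2, 0, chrom)


def rank_by_cadd(
    damaging: Iterable[DamagingVariant], top_n: int = 20
) -> pd.DataFrame:
    """Top-N damaging variants by descending CADD score.

    Ties broken by (chromosome, position) in genome order; variants
    without a CADD value are excluded.
    """
    scored = [dv for dv in damaging if dv.cadd is not None]
    if not scored:
        raise ValueError("no damaging variant carries a CADD score")
    scored.sort(key=lambda d: (-d.cadd, _chrom_sort_key(d.chrom), d.pos))
    rows = [
        {
            "gene": d.gene,
            "chrom": d.chrom,
            "pos": d.pos,
            "ref": d.ref,
            "alt": d.alt,
            "cadd": d.cadd,
        }
        for d in scored[:top_n]
    ]
    return pd.DataFrame(rows)
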