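"""Synthetic variant-catalog generator.

Emulates the statistical structure of a macaque population variant
catalog for end-to-end exercise of the constraint pipeline: per-gene
coding variant burdens X drawn negative-binomial (overdispersed; Poisson
is the large-dispersion limit), common functional counts Y ~
Binomial(X, p0·c) where c = ``constraint_factor`` < 1 for the
constrained gene fraction (constrained genes carry fewer common
functional variants than their burden predicts), gene sets drawn with a
configurable bias toward constrained genes, predicted-damaging flags on
functional variants, a disease-variant catalog with planted matches in
a toy shifted assembly, and a UCSC chain file connecting the two.

Everything derives from one seed: the same configuration produces a
byte-identical bundle.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .rvis import DEFAULT_MAF_THRESHOLD, GeneCounts

_NUCS = np.array(list("ACGT"))

#: Per-gene coding interval length and spacing on the toy chromosomes.
_GENE_SPAN = 4000
_GENE_PITCH = 5000

_DISEASES = ("ASD", "ID", "epilepsy", "schizophrenia")


@dataclass(frozen=True)
class SetSpec:
    """One synthetic gene set: name, size, constrained-gene bias."""

    name: str
    size: int
    fraction_from_constrained: float


@dataclass(frozen=True)
class QCNoise:
    """Fractions of extra variants generated to fail exactly one QC rule."""

    qual: float = 0.0
    depth: float = 0.0
    indel: float = 0.0
    nonautosome: float = 0.0


#: Genome fractions of curated NDD gene lists (set size / scored genes),
#: used to scale default synthetic sets to any genome size.
_SET_FRACTIONS = {
    "ASD": 0.044,
    "ID": 0.086,
    "epilepsy": 0.048,
    "schizophrenia": 0.111,
}


def default_set_specs(n_genes: int, bias: float = 0.8) -> tuple:
    """NDD-like sets scaled to the genome, biased toward constrained genes."""
    return tuple(
        SetSpec(name, max(2, int(round(frac * n_genes))), bias)
        for name, frac in _SET_FRACTIONS.items()
    )


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_chromosomes: int = 20
    mean_coding_variants_per_gene: float = 40.0
    dispersion: float = 5.0
    baseline_common_functional_rate: float = 0.4
    constrained_fraction: float = 0.25
    constraint_factor: float = 0.3
    set_specs: Optional[tuple] = None  # None -> default_set_specs(n_genes)
    damaging_rate: float = 0.1
    qc_noise: QCNoise = field(default_factory=QCNoise)
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    noncoding_rate: float = 2.0
    chain_offset: int = 1000
    n_disease_matches: int = 4
    n_disease_decoys: int = 20
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError(f"seed must be an integer, got {self.seed!r}")
        if self.set_specs is None:
            object.__setattr__(self, "set_specs", default_set_specs(self.n_genes))
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for name, v in (
            ("baseline_common_functional_rate", self.baseline_common_functional_rate),
            ("constrained_fraction", self.constrained_fraction),
            ("damaging_rate", self.damaging_rate),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.constraint_factor <= 1:
            raise ValueError("constraint_factor must be in [0, 1]")
        if self.mean_coding_variants_per_gene <= 0 or self.dispersion <= 0:
            raise ValueError("mean and dispersion must be positive")
        for spec in self.set_specs:
            if spec.size > self.n_genes:
                raise ValueError(
                    f"set {spec.name!r}: size {spec.size} exceeds "
                    f"n_genes={self.n_genes}"
                )
            if not 0 <= spec.fraction_from_constrained <= 1:
                raise ValueError(f"set {spec.name!r}: bad constrained fraction")
        for rule, frac in vars(self.qc_noise).items():
            if not 0 <= frac <= 1:
                raise ValueError(f"qc_noise.{rule} must be in [0, 1]")


@dataclass
class SimBundle:
    """Paths of one generated input bundle."""

    root: pathlib.Path
    vcf: pathlib.Path
    gene_models: pathlib.Path
    gene_sets: dict
    disease_variants: pathlib.Path
    damaging_variants: pathlib.Path
    chain: pathlib.Path
    truth: pathlib.Path
    metadata: pathlib.Path


def simulate_truth(config: SimConfig, rng: Optional[np.random.Generator] = None
                   ) -> pd.DataFrame:
    """Draw the per-gene ground truth (fast path, no files).

    Columns: gene, chrom, gene_index_on_chrom, constrained, true_rate,
    x, y, sets (comma-joined).  Y <= X by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(4, len(str(n)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, n + 1)])
    chrom_idx = np.arange(n) % config.n_chromosomes
    chroms = np.array([f"chr{i + 1}" for i in chrom_idx])
    gene_on_chrom = np.zeros(n, int)
    counters: dict[int, int] = {}
    for i, c in enumerate(chrom_idx):
        gene_on_chrom[i] = counters.get(c, 0)
        counters[c] = gene_on_chrom[i] + 1

    constrained = rng.random(n) < config.constrained_fraction
    p0 = config.baseline_common_functional_rate
    rate = np.where(constrained, p0 * config.constraint_factor, p0)

    # X ~ NB(mean mu, dispersion r): p = r/(r+mu)
    r = config.dispersion
    mu = config.mean_coding_variants_per_gene
    x = rng.negative_binomial(r, r / (r + mu), size=n)
    y = rng.binomial(x, rate)

    # biased set membership
    set_membership = [[] for _ in range(n)]
    constrained_idx = np.flatnonzero(constrained)
    unconstrained_idx = np.flatnonzero(~constrained)
    for spec in config.set_specs:
        n_con = min(int(round(spec.size * spec.fraction_from_constrained)),
                    len(constrained_idx))
        n_unc = min(spec.size - n_con, len(unconstrained_idx))
        chosen = np.concatenate(
            [
                rng.choice(constrained_idx, size=n_con, replace=False),
                rng.choice(unconstrained_idx, size=n_unc, replace=False),
            ]
        )
        for i in chosen:
            set_membership[i].append(spec.name)

    return pd.DataFrame(
        {
            "gene": genes,
            "chrom": chroms,
            "gene_index_on_chrom": gene_on_chrom,
            "constrained": constrained,
            "true_rate": rate,
            "x": x,
            "y": y,
            "sets": [",".join(m) for m in set_membership],
        }
    )


def counts_from_truth(truth: pd.DataFrame) -> list[GeneCounts]:
    """GeneCounts straight from a truth table (bypasses the VCF)."""
    return [
        GeneCounts(row.gene, int(row.x), int(row.y))
        for row in truth.itertuples(index=False)
    ]


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the truth table as TSV (lossless round trip via read_truth)."""
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"gene": str, "chrom": str, "sets": str},
    )
    if len(df):
        df["constrained"] = df["constrained"].astype(bool)
        df["sets"] = df["sets"].fillna("")
    return df


def _vcf_header(config: SimConfig, chrom_sizes: dict) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for chrom, size in chrom_sizes.items():
        h.contigs.add(chrom, length=size)
    h.info.add("GENE", 1, "String", "Annotated gene symbol")
    h.info.add("EFFECT", "A", "String",
               "Predicted effect (missense|lof|synonymous|noncoding)")
    h.info.add("AF", "A", "Float", "Alternate allele frequency")
    h.info.add("DMG", "A", "Integer", "Predicted damaging flag (0/1)")
    h.info.add("CADD", "A", "Float", "CADD phred-scaled score")
    h.info.add("DP", 1, "Integer", "Site depth")
    return h


def _draw_alleles(rng, n):
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    return _NUCS[ref_i], _NUCS[alt_i]


def generate_catalog(config: SimConfig, outdir) -> SimBundle:
    """Write the full synthetic input bundle to ``outdir``.

    Files: catalog.vcf, gene_models.tsv, gene_sets/<name>.txt,
    disease_variants.tsv, damaging_variants.tsv, assembly.chain,
    truth.tsv, metadata.json.  Deterministic in the seed.
    """
    rng = np.random.default_rng(config.seed)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "gene_sets").mkdir(exist_ok=True)

    truth = simulate_truth(config, rng)
    n = config.n_genes

    # gene models: fixed layout, _GENE_SPAN bp intervals at _GENE_PITCH
    starts = truth["gene_index_on_chrom"].to_numpy() * _GENE_PITCH + 1000
    ends = starts + _GENE_SPAN
    gene_models = pd.DataFrame(
        {"chrom": truth["chrom"], "start": starts, "end": ends,
         "gene": truth["gene"]}
    )
    genes_per_chrom = truth.groupby("chrom")["gene"].count()
    chrom_sizes = {
        f"chr{i + 1}": int(genes_per_chrom.get(f"chr{i + 1}", 0)) * _GENE_PITCH + 2000
        for i in range(config.n_chromosomes)
    }
    chrom_sizes["chrX"] = 200_000

    # per-gene variants
    maf = config.maf_threshold
    records = []  # (chrom, pos0, ref, alt, qual, dp, gene, effect, af, dmg, cadd)
    damaging_rows = []
    for row, start in zip(truth.itertuples(index=False), starts):
        x, y = int(row.x), int(row.y)
        n_noncoding = int(rng.poisson(config.noncoding_rate))
        total = x + n_noncoding
        if total == 0:
            continue
        pos = np.sort(rng.choice(_GENE_SPAN, size=min(total, _GENE_SPAN),
                                 replace=False))[:total] + start
        ref, alt = _draw_alleles(rng, total)
        effects = []
        afs = []
        for k in range(x):
            if k < y:  # common functional
                effects.append("missense" if rng.random() < 0.7 else "lof")
                afs.append(rng.uniform(maf, 0.5))
            else:  # never common functional: synonymous or rare functional
                if rng.random() < 0.5:
                    effects.append("synonymous")
                    afs.append(rng.uniform(1e-5, 0.5))
                else:
                    effects.append("missense" if rng.random() < 0.7 else "lof")
                    afs.append(rng.uniform(1e-5, maf * 0.999))
        effects += ["noncoding"] * n_noncoding
        afs += list(rng.uniform(1e-5, 0.5, n_noncoding))
        order = rng.permutation(total)  # decouple effect from position
        for j, k in enumerate(order):
            eff, af = effects[k], afs[k]
            dmg = int(eff in ("missense", "lof")
                      and rng.random() < config.damaging_rate)
            cadd = round(float(rng.uniform(15, 50)), 2) if dmg else None
            qual = round(float(rng.uniform(30, 60)), 1)
            dp = int(rng.integers(10, 51))
            rec = (row.chrom, int(pos[j]), str(ref[j]), str(alt[j]), qual, dp,
                   row.gene, eff, af, dmg, cadd)
            records.append(rec)
            if dmg:
                clinvar = int(rng.random() < 0.2)
                polyphen = int(rng.random() < 0.7)
                snpeff = int(rng.random() < 0.5)
                if not (clinvar or polyphen or snpeff):
                    polyphen = 1  # every damaging variant has >= 1 source
                damaging_rows.append(
                    {"chrom": row.chrom, "pos": int(pos[j]) + 1,
                     "ref": str(ref[j]), "alt": str(alt[j]), "gene": row.gene,
                     "clinvar": clinvar, "polyphen": polyphen,
                     "snpeff": snpeff, "cadd": cadd}
                )

    n_clean = len(records)
    qc_counts = {}
    noise = config.qc_noise
    gene_rows = list(truth.itertuples(index=False))

    def _noise_base(rule: str, frac: float) -> int:
        k = int(rng.binomial(n_clean, frac)) if frac > 0 else 0
        qc_counts[rule] = k
        return k

    for rule in ("qual", "depth", "indel", "nonautosome"):
        k = _noise_base(rule, getattr(noise, rule))
        for _ in range(k):
            g = gene_rows[int(rng.integers(0, n))]
            chrom = g.chrom
            start = 1000 + int(g.gene_index_on_chrom) * _GENE_PITCH
            pos0 = start + int(rng.integers(0, _GENE_SPAN))
            ref, alt = _draw_alleles(rng, 1)
            ref, alt = str(ref[0]), str(alt[0])
            qual = round(float(rng.uniform(30, 60)), 1)
            dp = int(rng.integers(10, 51))
            eff = "missense"
            af = float(rng.uniform(1e-5, 0.5))
            if rule == "qual":
                qual = round(float(rng.uniform(0, 29.9)), 1)
            elif rule == "depth":
                dp = int(rng.integers(0, 10)) if rng.random() < 0.5 \
                    else int(rng.integers(51, 200))
            elif rule == "indel":
                ref = ref + str(_NUCS[int(rng.integers(0, 4))])
            else:  # nonautosome
                chrom = "chrX"
                pos0 = int(rng.integers(0, chrom_sizes["chrX"] - 10))
            records.append((chrom, pos0, ref, alt, qual, dp, g.gene, eff, af,
                            0, None))

    chrom_order = {c: i for i, c in enumerate(chrom_sizes)}
    records.sort(key=lambda r: (chrom_order[r[0]], r[1], r[2], r[3]))

    vcf_path = outdir / "catalog.vcf"
    header = _vcf_header(config, chrom_sizes)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for chrom, pos0, ref, alt, qual, dp, gene, eff, af, dmg, cadd in records:
            rec = vf.new_record(
                contig=chrom, start=pos0, stop=pos0 + len(ref),
                alleles=(ref, alt), qual=qual,
            )
            rec.info["GENE"] = gene
            rec.info["EFFECT"] = (eff,)
            rec.info["AF"] = (af,)
            rec.info["DMG"] = (dmg,)
            if cadd is not None:
                rec.info["CADD"] = (cadd,)
            rec.info["DP"] = dp
            vf.write(rec)

    gene_models.to_csv(outdir / "gene_models.tsv", sep="\t", index=False)

    set_paths = {}
    for spec in config.set_specs:
        members = sorted(
            truth.loc[
                truth["sets"].str.split(",").apply(lambda s: spec.name in s),
                "gene",
            ]
        )
        p = outdir / "gene_sets" / f"{spec.name}.txt"
        p.write_text("\n".join(members) + "\n")
        set_paths[spec.name] = p

    dmg_df = pd.DataFrame(
        damaging_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "clinvar", "polyphen",
                 "snpeff", "cadd"],
    )
    dmg_df.to_csv(outdir / "damaging_variants.tsv", sep="\t", index=False)

    # chain file: one block per autosome shifting by chain_offset
    off = config.chain_offset
    chain_lines = []
    for cid, (chrom, size) in enumerate(
        ((c, s) for c, s in chrom_sizes.items() if c != "chrX"), start=1
    ):
        q_size = size + abs(off)
        if off >= 0:
            t_start, t_end, q_start, q_end = 0, size, off, off + size
        else:
            t_start, t_end, q_start, q_end = -off, size, 0, size + off
        block = t_end - t_start
        chain_lines.append(
            f"chain 1000 {chrom} {size} + {t_start} {t_end} "
            f"{chrom} {q_size} + {q_start} {q_end} {cid}"
        )
        chain_lines.append(str(block))
        chain_lines.append("")
    chain_path = outdir / "assembly.chain"
    chain_path.write_text("\n".join(chain_lines))

    # disease catalog: planted matches (lifted damaging variants) + decoys
    disease_rows = []
    n_match = min(config.n_disease_matches, len(dmg_df))
    planted_keys = set()
    if n_match:
        pick = rng.choice(len(dmg_df), size=n_match, replace=False)
        for j, i in enumerate(sorted(int(v) for v in pick)):
            r = dmg_df.iloc[i]
            key = (r["chrom"], int(r["pos"]) + off, r["ref"], r["alt"])
            planted_keys.add(key)
            disease_rows.append(
                {"chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                 "disease": _DISEASES[j % len(_DISEASES)]}
            )
    lifted_all = {
        (r.chrom, int(r.pos) + off, r.ref, r.alt)
        for r in dmg_df.itertuples(index=False)
    }
    autosomes = [c for c in chrom_sizes if c != "chrX"]
    for j in range(config.n_disease_decoys):
        while True:
            chrom = autosomes[int(rng.integers(0, len(autosomes)))]
            pos = int(rng.integers(1, chrom_sizes[chrom])) + max(off, 0)
            ref, alt = _draw_alleles(rng, 1)
            key = (chrom, pos, str(ref[0]), str(alt[0]))
            if key not in lifted_all:
                break
        disease_rows.append(
            {"chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
             "disease": _DISEASES[j % len(_DISEASES)]}
        )
    pd.DataFrame(
        disease_rows, columns=["chrom", "pos", "ref", "alt", "disease"]
    ).to_csv(outdir / "disease_variants.tsv", sep="\t", index=False)

    write_truth(truth, outdir / "truth.tsv")

    meta = {
        "seed": int(config.seed),
        "n_clean_variants": int(n_clean),
        "qc_noise_counts": qc_counts,
        "n_planted_disease_matches": int(n_match),
        "n_disease_decoys": int(config.n_disease_decoys),
        "chain_offset": int(off),
        "config": _config_dict(config),
    }
    meta_path = outdir / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    return SimBundle(
        root=outdir,
        vcf=vcf_path,
        gene_models=outdir / "gene_models.tsv",
        gene_sets=set_paths,
        disease_variants=outdir / "disease_variants.tsv",
        damaging_variants=outdir / "damaging_variants.tsv",
        chain=chain_path,
        truth=outdir / "truth.tsv",
        metadata=meta_path,
    )


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["set_specs"] = [asdict(s) if not isinstance(s, dict) else s
                      for s in config.set_specs]
    return d


def read_gene_models(path) -> pd.DataFrame:
    """BED-like TSV: chrom, start, end, gene (0-based half-open)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
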