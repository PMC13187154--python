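"""Orthogroup-level expression: count aggregation, TPM, cross-species contrast.

Per-gene RNA-seq counts cannot be compared directly between species whose gene
sets differ; the unit of comparison here is the orthogroup.  For every
orthogroup and sample we sum the counts of that species' member genes, and for
every orthogroup and species we sum the member gene lengths.  TPM is then
computed at the orthogroup level: rate = count / length, scaled so each
sample's rates sum to one million.  Expression of each non-reference species is
contrasted against a reference species (the fastest fermenter in the study
design) by a Welch t-test on log2(TPM + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneCountTable:
    """One sample's per-gene counts (summary ``__*`` rows already removed)."""

    sample: str
    species: str
    counts: pd.Series  # index: gene id, values: nonnegative numbers

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            bad = self.counts[self.counts < 0].index.tolist()
            raise ValueError(f"sample {self.sample}: negative counts for {bad[:5]}")


OrthogroupMap = Mapping[str, Mapping[str, list[str]]]  # og -> species -> genes


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, sample: str, species: str) -> GeneCountTable:
    """Read a two-column (gene id, count) file in the HTSeq-count dialect.

    Summary rows whose id begins with ``__`` (``__no_feature`` etc.) are
    dropped and their totals logged.  Duplicate gene ids, negative counts and
    non-numeric counts are errors reported with their line number.  Fractional
    counts (from fraction-of-multimapper counting) are accepted with a warning.
    """
    path = Path(path)
    genes: dict[str, float] = {}
    n_fractional = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            gene, text = parts[0].strip(), parts[1].strip()
            try:
                value = float(text)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric count {text!r}") from err
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count for {gene}")
            if gene.startswith("__"):
                logger.info("%s: summary row %s = %g", path.name, gene, value)
                continue
            if gene in genes:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene}")
            if value != int(value):
                n_fractional += 1
            genes[gene] = value
    if n_fractional:
        logger.warning("%s: %d fractional counts accepted as-is", path.name, n_fractional)
    if not genes:
        logger.warning("%s: empty count table", path.name)
    return GeneCountTable(sample=sample, species=species, counts=pd.Series(genes, dtype=float))


def read_orthogroups(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Read an Orthogroups.tsv: first column orthogroup id, one column per
    species, cells are ``", "``-joined gene lists (empty cell = absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    species_cols = list(df.columns[1:])
    out: dict[str, dict[str, list[str]]] = {}
    seen_genes: dict[str, set[str]] = {sp: set() for sp in species_cols}
    for _, row in df.iterrows():
        og = row[og_col]
        members: dict[str, list[str]] = {}
        for sp in species_cols:
            genes = [g for g in (s.strip() for s in row[sp].split(",")) if g]
            if genes:
                dup = seen_genes[sp].intersection(genes)
                if dup:
                    raise ValueError(
                        f"{path}: gene(s) {sorted(dup)[:5]} of {sp} assigned to more "
                        f"than one orthogroup"
                    )
                seen_genes[sp].update(genes)
                members[sp] = genes
        out[og] = members
    return out


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"gene", "length"}.issubset(df.columns):
        raise ValueError(f"{path}: length table needs columns gene, length")
    s = df.set_index("gene")["length"].astype(float)
    if (s <= 0).any():
        raise ValueError(f"{path}: non-positive gene lengths present")
    return s


def _merge_intervals(ivals: list[tuple[int, int]]) -> int:
    """Total covered length of 1-based inclusive intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(ivals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s + 1
    return total


def lengths_from_gff(path: str | Path, feature: str = "gene_span") -> pd.Series:
    """Gene lengths from a GFF3 annotation.

    ``gene_span`` uses end - start + 1 of each ``gene`` feature (GFF3 1-based
    inclusive coordinates); ``exon_union`` uses the total length of the union
    of each gene's exon intervals, resolving exon parentage through mRNA
    features where necessary.
    """
    import gffutils

    if feature not in {"gene_span", "exon_union"}:
        raise ValueError(f"unknown length feature {feature!r}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        if gene.end < gene.start:
            raise ValueError(f"{path}: gene {gene.id} has end < start")
        if feature == "gene_span":
            lengths[gene.id] = gene.end - gene.start + 1
        else:
            exons = [(f.start, f.end) for f in db.children(gene.id, featuretype="exon")]
            if not exons:
                raise ValueError(f"{path}: gene {gene.id} has no exon children")
            lengths[gene.id] = _merge_intervals(exons)
    if not lengths:
        raise ValueError(f"{path}: no gene features found")
    return pd.Series(lengths, dtype=float)


# ---------------------------------------------------------------------------
# aggregation and TPM
# ---------------------------------------------------------------------------


def aggregate_orthogroups(
    counts: Iterable[GeneCountTable],
    lengths: pd.Series,
    og_map: OrthogroupMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum counts and lengths to orthogroup level.

    Returns ``(count_df, length_df)``: counts as an orthogroup x sample table,
    lengths as an orthogroup x species table (NaN where the species has no
    members).  Genes that belong to an orthogroup but lack a length are an
    error; genes in no orthogroup are tallied per sample and logged.
    """
    counts = list(counts)
    gene_to_og: dict[tuple[str, str], str] = {}
    for og, members in og_map.items():
        for sp, genes in members.items():
            for g in genes:
                gene_to_og[(sp, g)] = og
    missing_lengths = sorted(
        {g for (sp, g) in gene_to_og if g not in lengths.index}
    )
    if missing_lengths:
        raise ValueError(
            f"{len(missing_lengths)} orthogroup member genes lack lengths, e.g. "
            f"{missing_lengths[:5]}"
        )
    ogs = list(og_map)
    samples = [t.sample for t in counts]
    count_df = pd.DataFrame(0.0, index=ogs, columns=samples)
    for table in counts:
        unassigned = 0.0
        total = float(table.counts.sum())
        for gene, value in table.counts.items():
            og = gene_to_og.get((table.species, gene))
            if og is None:
                unassigned += value
                continue
            count_df.at[og, table.sample] += value
        if total > 0:
            logger.info(
                "sample %s: %.1f%% of counts unassigned to orthogroups",
                table.sample, 100.0 * unassigned / total,
            )
    species_list = sorted({t.species for t in counts} | {
        sp for members in og_map.values() for sp in members
    })
    length_df = pd.DataFrame(np.nan, index=ogs, columns=species_list)
    for og, members in og_map.items():
        for sp, genes in members.items():
            # an empty member list means the orthogroup is absent from that
            # species: its length stays undefined rather than becoming 0
            if genes and sp in length_df.columns:
                length_df.at[og, sp] = float(lengths.loc[genes].sum())
    return count_df, length_df


def compute_tpm(
    count_df: pd.DataFrame,
    length_df: pd.DataFrame,
    sample_species: Mapping[str, str],
) -> pd.DataFrame:
    """Orthogroup TPM per sample, in long format.

    For each sample, only orthogroups whose length is defined in that sample's
    species enter the normalization; excluded orthogroups with nonzero counts
    are logged as missing.  TPM = (count/length) / sum(count/length) * 1e6,
    so each sample's TPM sums to one million over its normalized orthogroups.
    """
    rows = []
    for sample in count_df.columns:
        species = sample_species[sample]
        if species not in length_df.columns:
            raise ValueError(f"sample {sample}: species {species} has no length data")
        lens = length_df[species]
        counts = count_df[sample]
        defined = lens.notna()
        skipped = counts[~defined & (counts > 0)]
        if len(skipped):
            logger.info(
                "sample %s: %d orthogroups with counts but no %s length excluded",
                sample, len(skipped), species,
            )
        c = counts[defined].to_numpy(dtype=float)
        l = lens[defined].to_numpy(dtype=float)
        if c.sum() == 0:
            raise ValueError(f"sample {sample}: all counts zero, TPM undefined")
        rate = c / l
        tpm = rate / rate.sum() * 1e6
        for og, cnt, length, t in zip(count_df.index[defined], c, l, tpm):
            rows.append({"orthogroup": og, "sample": sample, "species": species,
                         "count": cnt, "length": length, "tpm": t})
    return pd.DataFrame(rows)


def compare_to_reference(
    expr: pd.DataFrame,
    reference: str,
    log2_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test of each species' orthogroup TPM against the reference.

    The test statistic is computed on log2(TPM + pseudocount) replicate values;
    the reported effect size is log2 of the ratio of group means on the same
    shifted scale, so identical groups give exactly 0.  Species or orthogroups
    with fewer than two replicates on either side are skipped with a logged
    reason.  Benjamini-Hochberg adjusted p-values are added per species.
    """
    if reference not in set(expr["species"]):
        raise ValueError(f"reference species {reference!r} not present")
    rows = []
    pivot = expr.pivot_table(index="orthogroup", columns="sample", values="tpm")
    sample_species = expr.drop_duplicates("sample").set_index("sample")["species"]
    ref_samples = sample_species[sample_species == reference].index
    if len(ref_samples) < 2:
        raise ValueError(f"reference {reference} has {len(ref_samples)} replicates; need >= 2")
    for species in sorted(set(sample_species) - {reference}):
        other_samples = sample_species[sample_species == species].index
        if len(other_samples) < 2:
            logger.info("species %s has <2 replicates; comparison skipped", species)
            continue
        for og in pivot.index:
            ref_v = pivot.loc[og, ref_samples].dropna().to_numpy(dtype=float)
            oth_v = pivot.loc[og, other_samples].dropna().to_numpy(dtype=float)
            if len(ref_v) < 2 or len(oth_v) < 2:
                logger.info("orthogroup %s vs %s: <2 usable replicates; skipped", og, species)
                continue
            lf = float(
                np.log2(oth_v.mean() + log2_pseudocount)
                - np.log2(ref_v.mean() + log2_pseudocount)
            )
            a = np.log2(ref_v + log2_pseudocount)
            b = np.log2(oth_v + log2_pseudocount)
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                # Welch statistic is 0/0 for two constant groups
                t_stat, p = (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
            else:
                t_stat, p = stats.ttest_ind(b, a, equal_var=False)
            rows.append({"orthogroup": og, "species": species, "log2fc": lf,
                         "t": float(t_stat), "p": float(p),
                         "n_ref": len(ref_v), "n_other": len(oth_v)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.nan
        for species, idx in out.groupby("species").groups.items():
            out.loc[idx, "p_adj"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    return out
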