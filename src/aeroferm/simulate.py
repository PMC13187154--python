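"""Seeded synthetic inputs, with recorded ground truth, for every pipeline stage.

Each generator emulates the corresponding assay's study conditions:

- plates: phenol-red absorbance kinetics, 31 reads over 90 min, three
  biological replicates of paired carbon/water wells, with a true dextrose-
  dependent ECAR of -0.032 pH/h (a rapid fermenter) and absorbance noise of
  0.005 sd by default;
- comparative data: a pure-birth tree scaled to depth 1, gene-family copy
  numbers with clade-shifted Poisson means (so the predictor itself carries
  phylogenetic signal), and a trait built as beta * total copies plus Brownian
  noise with tip variance sigma^2;
- expression: four species in two phenotype groups, four replicates each,
  negative-binomial per-gene counts summed into 1-3 member orthogroups, with a
  4x planted fold change on designated orthogroups;
- genomes: uniform-background contigs with annotated genes on both strands and
  a known number of non-overlapping Gal4p-consensus instances implanted in
  each 1 kb upstream window (optionally on a G-free background so spurious
  matches are impossible).

A single root seed derives an independent substream per generator
(``default_rng([seed, key])`` with a fixed key), so adding generators never
perturbs existing outputs, and identical configurations yield byte-identical
files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import dendropy
import numpy as np
import pandas as pd

from . import motifs as motifmod
from .comparative import bm_covariance
from .expression import GeneCountTable
from .motifs import GeneModel, parse_motif

# fixed substream keys; never renumber
_KEY_PLATE, _KEY_TREE, _KEY_EXPR, _KEY_GENOME = 11, 23, 37, 53


@dataclass
class SimConfig:
    """Study-condition parameters for all four generators."""

    seed: int = 0

    # --- plate assay ---
    # per-strain true (carbon, control) acidification slopes in pH/h; the
    # default strain is a rapid fermenter with true ECAR -0.032 pH/h
    true_slopes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Sat_dispora": (-0.034, -0.002)}
    )
    replicates: int = 3
    n_timepoints: int = 31
    t_max_min: float = 90.0
    ph0: float = 6.8
    absorbance_sd: float = 0.005
    calibration_sd: float = 0.0
    curve_slope: float = 1.0      # pH per absorbance unit
    curve_intercept: float = 6.0  # so pH 6.5-7.5 spans A560 0.5-1.5
    calibration_ph: tuple[float, ...] = (6.5, 6.75, 7.0, 7.25, 7.5)

    # --- tree / trait / counts ---
    n_taxa: int = 32
    n_families: int = 13           # one per glycolytic enzymatic step
    family_base_mean: float = 2.0  # copies per family in an average yeast
    clade_shift: float = 2.0       # extra mean copies in the shifted clade
    beta: float = -0.001           # pH/h per extra gene copy
    bm_sigma2: float = 1e-4        # trait variance at the tips (depth-1 tree)

    # --- expression ---
    species_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "rapid": ("Sat_dispora", "Sat_hagleri"),
            "low": ("Sat_mendoncae", "Sat_silvae"),
        }
    )
    reference_species: str = "Sat_dispora"
    samples_per_species: int = 4
    n_orthogroups: int = 200
    n_planted: int = 10
    fold_change: float = 4.0       # planted low-vs-rapid fold change
    nb_dispersion: float = 0.1
    mean_log_mu: float = 5.0       # lognormal location of orthogroup mean counts
    mean_log_sd: float = 1.0
    max_genes_per_og: int = 3
    length_range: tuple[int, int] = (500, 5000)

    # --- genome / motifs ---
    n_contigs: int = 2
    genes_per_contig: int = 4
    implants_per_gene: int = 2
    motif: str = motifmod.DEFAULT_MOTIF
    upstream: int = 1000
    gene_length_range: tuple[int, int] = (900, 1500)
    g_free_background: bool = False
    genome_species: str = "Sat_dispora"
    families: tuple[str, ...] = ("TDH", "ENO", "PYK", "GPM", "HXK", "PDC", "PFK", "FBA")

    def __post_init__(self) -> None:
        for name in ("n_taxa", "n_families", "replicates", "n_timepoints",
                     "n_orthogroups", "samples_per_species", "n_contigs",
                     "genes_per_contig"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.absorbance_sd < 0 or self.calibration_sd < 0 or self.nb_dispersion < 0:
            raise ValueError("noise sds and dispersion must be >= 0")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be >= 0")


def _rng(config: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), key])


def _write_truth(truth: dict, outdir: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    (outdir / "truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True, default=default) + "\n"
    )


# ---------------------------------------------------------------------------
# plate assay
# ---------------------------------------------------------------------------


class PlateSim(NamedTuple):
    plate: pd.DataFrame
    layout: pd.DataFrame
    calibration: pd.DataFrame
    truth: dict


def simulate_plate(config: SimConfig, outdir: str | Path | None = None) -> PlateSim:
    """Plate kinetics with known per-well acidification slopes.

    pH trajectories are linear, pH(t) = pH0 + slope * t, inverted through the
    configured standard curve to absorbance, plus Gaussian read noise.
    """
    if config.curve_slope == 0:
        raise ValueError("standard curve slope must be nonzero")
    rng = _rng(config, _KEY_PLATE)
    t_min = np.linspace(0.0, config.t_max_min, config.n_timepoints)
    calib_a = (np.asarray(config.calibration_ph) - config.curve_intercept) / config.curve_slope
    calib_a = calib_a + rng.normal(0.0, config.calibration_sd, size=len(calib_a))
    calibration = pd.DataFrame({"ph": config.calibration_ph, "a560": calib_a})

    plate_rows, layout_rows = [], []
    truth_wells = {}
    well_no = 0
    for strain, (slope_c, slope_w) in config.true_slopes.items():
        for rep in range(1, config.replicates + 1):
            for condition, slope in (("carbon", slope_c), ("control", slope_w)):
                row_letter = "ABCDEFGH"[well_no // 12]
                well = f"{row_letter}{well_no % 12 + 1}"
                well_no += 1
                ph = config.ph0 + slope * (t_min / 60.0)
                a = (ph - config.curve_intercept) / config.curve_slope
                a = a + rng.normal(0.0, config.absorbance_sd, size=len(a))
                for t, av in zip(t_min, a):
                    plate_rows.append({"well": well, "time_min": t, "a560": av})
                layout_rows.append({"well": well, "strain": strain,
                                    "condition": condition, "replicate": rep})
                truth_wells[well] = {"strain": strain, "condition": condition,
                                     "replicate": rep, "true_slope_ph_per_h": slope}
    plate = pd.DataFrame(plate_rows)
    layout = pd.DataFrame(layout_rows)
    truth = {
        "true_slopes": {s: list(v) for s, v in config.true_slopes.items()},
        "true_ecar": {s: v[0] - v[1] for s, v in config.true_slopes.items()},
        "wells": truth_wells,
        "curve": {"slope": config.curve_slope, "intercept": config.curve_intercept},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plate.to_csv(outdir / "plate.csv", index=False, float_format="%.10g")
        layout.to_csv(outdir / "layout.csv", index=False)
        calibration.to_csv(outdir / "calibration.csv", index=False, float_format="%.10g")
        _write_truth(truth, outdir)
    return PlateSim(plate, layout, calibration, truth)


# ---------------------------------------------------------------------------
# tree, trait, counts
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("time", "children", "label")

    def __init__(self, time: float) -> None:
        self.time = time
        self.children: list[_Lineage] = []
        self.label: str | None = None


def _yule_newick(n_taxa: int, rng: np.random.Generator) -> str:
    """Pure-birth (Yule) tree with unit birth rate, scaled to total depth 1."""
    root = _Lineage(0.0)
    a, b = _Lineage(0.0), _Lineage(0.0)
    root.children = [a, b]
    # active lineages are pending tips; splitting one turns it into an
    # internal node with two fresh pending children
    active = [a, b]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active[idx]
        node.time = t
        c1, c2 = _Lineage(t), _Lineage(t)
        node.children = [c1, c2]
        active[idx] = c1
        active.append(c2)
    total = t + rng.exponential(1.0 / n_taxa)
    for i, leaf in enumerate(active):
        leaf.time = total
        leaf.label = f"sp{i + 1:03d}"

    def emit(node: _Lineage, parent_time: float) -> str:
        bl = (node.time - parent_time) / total
        if not node.children:
            return f"{node.label}:{bl:.10f}"
        inner = ",".join(emit(c, node.time) for c in node.children)
        return f"({inner}):{bl:.10f}"

    inner = ",".join(emit(c, 0.0) for c in root.children)
    return f"({inner});"


def simulate_yule_tree(n_taxa: int, rng: np.random.Generator) -> dendropy.Tree:
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    return dendropy.Tree.get(
        data=_yule_newick(n_taxa, rng), schema="newick",
        preserve_underscores=True, rooting="force-rooted",
    )


class TreeSim(NamedTuple):
    tree: dendropy.Tree
    counts: pd.DataFrame
    trait: pd.DataFrame
    truth: dict


def simulate_tree_trait_counts(config: SimConfig, outdir: str | Path | None = None) -> TreeSim:
    """Tree + gene-family counts + trait with known regression coefficient.

    Copy numbers are Poisson with a per-family mean that is shifted upward
    inside one randomly chosen clade (emulating a duplication inherited by
    descent, e.g. a WGD); the trait is beta * total copies plus Brownian noise
    drawn from N(0, sigma2 * C).  Taxa are additionally labeled with the two
    root-clade "orders" for subset analyses.
    """
    if config.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = _rng(config, _KEY_TREE)
    tree = simulate_yule_tree(config.n_taxa, rng)
    C, labels = bm_covariance(tree)
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}

    # clades (tip sets of internal nodes, excluding root and single tips)
    clades: list[list[int]] = []
    for node in tree.postorder_internal_node_iter(exclude_seed_node=True):
        tips = [idx[l.taxon.label] for l in node.leaf_iter()]
        if 2 <= len(tips) <= n - 2:
            clades.append(tips)

    fam_names = [f"fam{j + 1:02d}" for j in range(config.n_families)]
    counts = np.zeros((n, config.n_families), dtype=int)
    shifted: dict[str, list[str]] = {}
    for j, fam in enumerate(fam_names):
        means = np.full(n, config.family_base_mean)
        if clades and config.clade_shift > 0:
            clade = clades[int(rng.integers(len(clades)))]
            means[clade] += config.clade_shift
            shifted[fam] = [labels[i] for i in clade]
        counts[:, j] = rng.poisson(means)
    counts_df = pd.DataFrame(counts, columns=fam_names)
    counts_df.insert(0, "species", labels)

    # two root clades as taxonomic "orders"
    root_kids = tree.seed_node.child_nodes()
    order = np.array(["order_B"] * n, dtype=object)
    for l in root_kids[0].leaf_iter():
        order[idx[l.taxon.label]] = "order_A"
    counts_df["order"] = order

    total = counts.sum(axis=1)
    if config.bm_sigma2 > 0:
        L = np.linalg.cholesky(C)
        noise = math.sqrt(config.bm_sigma2) * (L @ rng.standard_normal(n))
    else:
        noise = np.zeros(n)
    y = config.beta * total + noise
    trait_df = pd.DataFrame({"species": labels, "mean_ecar": y})
    truth = {
        "beta": config.beta,
        "sigma2": config.bm_sigma2,
        "shifted_clades": shifted,
        "total_counts": {l: int(t) for l, t in zip(labels, total)},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(
            tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        )
        counts_df.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        trait_df.to_csv(outdir / "trait.tsv", sep="\t", index=False, float_format="%.10g")
        _write_truth(truth, outdir)
    return TreeSim(tree, counts_df, trait_df, truth)


def draw_bm_noise(C: np.ndarray, sigma2: float, rng: np.random.Generator,
                  size: int = 1) -> np.ndarray:
    """``size`` independent Brownian tip-noise vectors ~ N(0, sigma2 C)."""
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((size, C.shape[0]))
    return math.sqrt(sigma2) * (z @ L.T)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


class ExprSim(NamedTuple):
    counts: list[GeneCountTable]
    sample_sheet: pd.DataFrame
    og_map: dict[str, dict[str, list[str]]]
    lengths: pd.Series
    truth: dict


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # var = mean + dispersion * mean^2
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(config: SimConfig, outdir: str | Path | None = None) -> ExprSim:
    """Cross-species count data with planted orthogroup-level fold changes.

    Every orthogroup has 1-3 member genes per species with lengths uniform in
    the configured range; per-gene counts are negative binomial around the
    orthogroup mean split across members.  Designated orthogroups carry the
    planted fold change in the "low"-phenotype group relative to the "rapid"
    (reference) group.
    """
    rng = _rng(config, _KEY_EXPR)
    species = [sp for grp in config.species_groups.values() for sp in grp]
    group_of = {sp: g for g, members in config.species_groups.items() for sp in members}
    ogs = [f"OG{i:07d}" for i in range(config.n_orthogroups)]
    planted = sorted(rng.choice(config.n_orthogroups, size=config.n_planted,
                                replace=False).tolist()) if config.n_planted else []
    og_mean = np.exp(rng.normal(config.mean_log_mu, config.mean_log_sd,
                                size=config.n_orthogroups))

    og_map: dict[str, dict[str, list[str]]] = {}
    lengths: dict[str, int] = {}
    members_per: dict[tuple[str, str], list[str]] = {}
    for i, og in enumerate(ogs):
        og_map[og] = {}
        for sp in species:
            k = int(rng.integers(1, config.max_genes_per_og + 1))
            genes = [f"{sp}_g{i:05d}_{j + 1}" for j in range(k)]
            og_map[og][sp] = genes
            members_per[(og, sp)] = genes
            lo, hi = config.length_range
            for g in genes:
                lengths[g] = int(rng.integers(lo, hi + 1))

    tables: list[GeneCountTable] = []
    sheet_rows = []
    fold_by_og = {ogs[i]: config.fold_change for i in planted}
    for sp in species:
        fold_active = group_of[sp] == "low"
        for r in range(1, config.samples_per_species + 1):
            sample = f"{sp}_r{r}"
            gene_counts: dict[str, float] = {}
            for i, og in enumerate(ogs):
                abundance = og_mean[i]  # expected reads per kb of transcript
                if fold_active and og in fold_by_og:
                    abundance = abundance * fold_by_og[og]
                genes = members_per[(og, sp)]
                # reads scale with transcript length; every copy is expressed at
                # the orthogroup's level, so sum(count)/sum(length) estimates the
                # abundance regardless of copy number or length differences
                per_gene_mean = np.array(
                    [abundance * lengths[g] / 1000.0 for g in genes]
                )
                draws = _nb_draw(rng, per_gene_mean, config.nb_dispersion)
                for g, c in zip(genes, draws):
                    gene_counts[g] = float(c)
            tables.append(GeneCountTable(sample=sample, species=sp,
                                         counts=pd.Series(gene_counts, dtype=float)))
            sheet_rows.append({"sample": sample, "species": sp,
                               "group": group_of[sp],
                               "file": f"counts/{sample}.counts.tsv"})
    sheet = pd.DataFrame(sheet_rows)
    truth = {
        "planted_orthogroups": [ogs[i] for i in planted],
        "fold_change": config.fold_change,
        "affected_group": "low",
        "reference_species": config.reference_species,
        "og_means": {og: float(m) for og, m in zip(ogs, og_mean)},
    }
    lengths_s = pd.Series(lengths, dtype=float)
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "counts").mkdir(parents=True, exist_ok=True)
        for t in tables:
            lines = [f"{g}\t{int(c) if c == int(c) else c}" for g, c in t.counts.items()]
            lines.append("__no_feature\t0")
            lines.append("__ambiguous\t0")
            (outdir / "counts" / f"{t.sample}.counts.tsv").write_text("\n".join(lines) + "\n")
        sheet.to_csv(outdir / "samples.csv", index=False)
        og_rows = []
        for og in ogs:
            row = {"Orthogroup": og}
            for sp in species:
                row[sp] = ", ".join(og_map[og].get(sp, []))
            og_rows.append(row)
        pd.DataFrame(og_rows).to_csv(outdir / "Orthogroups.tsv", sep="\t", index=False)
        lengths_s.rename_axis("gene").rename("length").astype(int).to_csv(
            outdir / "lengths.tsv", sep="\t"
        )
        _write_truth(truth, outdir)
    return ExprSim(tables, sheet, og_map, lengths_s, truth)


# ---------------------------------------------------------------------------
# genome with implanted motifs
# ---------------------------------------------------------------------------


class GenomeSim(NamedTuple):
    contigs: dict[str, str]
    genes: list[GeneModel]
    family_map: dict[str, str]
    truth: dict


def simulate_genome_with_motifs(config: SimConfig, outdir: str | Path | None = None) -> GenomeSim:
    """Mini-genome with a known number of consensus sites per promoter.

    Genes alternate strands along each contig with well over 1 kb spacing;
    each gene's flat 1 kb upstream window receives the configured number of
    non-overlapping motif instances at recorded offsets (offsets are in
    promoter coordinates, 0 = the 5' end of the extracted window).  With
    ``g_free_background`` the background alphabet excludes G, so no spurious
    site can occur on either strand and counts equal implants exactly.
    """
    rng = _rng(config, _KEY_GENOME)
    motif = parse_motif(config.motif)
    mlen = len(motif)
    k = config.implants_per_gene
    if k * mlen > config.upstream:
        raise ValueError(
            f"{k} implants of length {mlen} exceed the {config.upstream} bp window"
        )
    alphabet = np.array(list("ACT" if config.g_free_background else "ACGT"))
    block = config.upstream + config.gene_length_range[1] + 1600
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    family_map: dict[str, str] = {}
    truth_genes: dict[str, dict] = {}
    gi = 0
    for c in range(config.n_contigs):
        contig = f"contig{c + 1}"
        clen = config.genes_per_contig * block + 500
        seq = rng.choice(alphabet, size=clen)
        for slot in range(config.genes_per_contig):
            gi += 1
            gene_id = f"{config.genome_species}_g{gi:03d}"
            b0 = slot * block  # 0-based block offset
            glen = int(rng.integers(*config.gene_length_range))
            strand = "+" if (gi % 2 == 1) else "-"
            if strand == "+":
                start = b0 + config.upstream + 1  # 1-based
                end = start + glen - 1
                prom_g0 = b0  # 0-based genomic start of the upstream window
            else:
                start = b0 + 1
                end = b0 + glen
                prom_g0 = end  # window is [end+1 .. end+upstream], 0-based start = end
            # implant instances at non-overlapping promoter offsets
            offsets: list[int] = []
            guard = 0
            while len(offsets) < k:
                cand = int(rng.integers(0, config.upstream - mlen + 1))
                if all(abs(cand - o) >= mlen for o in offsets):
                    offsets.append(cand)
                guard += 1
                if guard > 10000:
                    raise ValueError("could not place non-overlapping implants")
            offsets.sort()
            instances = []
            for off in offsets:
                inst = "".join(
                    str(rng.choice(sorted(s))) for s in motif.base_sets
                )
                instances.append(inst)
                if strand == "+":
                    g0 = prom_g0 + off
                    seq[g0 : g0 + mlen] = list(inst)
                else:
                    # promoter offset off corresponds to the genomic window whose
                    # reverse complement starts off bases into the extracted seq
                    g_end0 = prom_g0 + config.upstream - off  # exclusive
                    seq[g_end0 - mlen : g_end0] = list(motifmod.reverse_complement(inst))
            genes.append(GeneModel(gene=gene_id, contig=contig, start=start,
                                   end=end, strand=strand))
            family_map[gene_id] = config.families[(gi - 1) % len(config.families)]
            truth_genes[gene_id] = {"implant_offsets": offsets,
                                    "implant_instances": instances,
                                    "strand": strand}
        contigs[contig] = "".join(seq)
    truth = {
        "motif": config.motif,
        "implants_per_gene": k,
        "g_free_background": config.g_free_background,
        "genes": truth_genes,
        "species": config.genome_species,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with (outdir / "genome.fa").open("w") as fh:
            for name in sorted(contigs):
                fh.write(f">{name}\n")
                s = contigs[name]
                for i in range(0, len(s), 70):
                    fh.write(s[i : i + 70] + "\n")
        with (outdir / "genes.gff3").open("w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.contig}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene}\n"
                )
                fh.write(
                    f"{g.contig}\tsim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                    f"ID=cds-{g.gene};Parent={g.gene}\n"
                )
        pd.DataFrame(
            {"gene": list(family_map), "family": list(family_map.values())}
        ).to_csv(outdir / "family_map.tsv", sep="\t", index=False)
        _write_truth(truth, outdir)
    return GenomeSim(contigs, genes, family_map, truth)
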