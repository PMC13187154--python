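"""Stage 2 — glycolytic gene-family copy number vs ECAR, with and without
phylogenetic correction.

Simulates a 32-taxon comparative dataset (pure-birth tree, clade-shifted
Poisson copy numbers with a true trait coefficient of -0.001 pH/h per copy,
Brownian trait noise), then runs plain Pearson correlations per family and
PGLS (lambda = 1) per family plus the total-copy-number regression, for all
taxa and for the two root-clade "orders" separately.
"""

from pathlib import Path

from aeroferm import comparative
from aeroferm.simulate import SimConfig, simulate_tree_trait_counts

OUT = Path(__file__).resolve().parent.parent / "results" / "comparative"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=202)
    sim = simulate_tree_trait_counts(cfg, outdir=OUT / "inputs")

    subsets = {"all": None}
    for level, grp in sim.counts.groupby("order"):
        if len(grp) >= 6:
            subsets[str(level)] = grp["species"].tolist()

    for name, subset in subsets.items():
        pe = comparative.pearson_by_family(sim.trait, sim.counts, subset=subset)
        pg = comparative.pgls_by_family(sim.trait, sim.counts, sim.tree,
                                        lam=1.0, subset=subset)
        pe.to_csv(OUT / f"pearson_{name}.tsv", sep="\t", index=False)
        pg.to_csv(OUT / f"pgls_{name}.tsv", sep="\t", index=False)

    pe = comparative.pearson_by_family(sim.trait, sim.counts).set_index("family")
    pg = comparative.pgls_by_family(sim.trait, sim.counts, sim.tree).set_index("family")
    tot_pe, tot_pg = pe.loc["total"], pg.loc["total"]
    print(f"total glycolytic copies vs ECAR (true beta = {cfg.beta}):")
    print(f"  Pearson r = {tot_pe['r']:+.3f} (p = {tot_pe['p']:.2e}{tot_pe['stars']})")
    print(f"  PGLS beta = {tot_pg['beta']:+.5f} +/- {tot_pg['se']:.5f}, "
          f"R = {tot_pg['r_signed']:+.3f} (p = {tot_pg['p']:.2e}{tot_pg['stars']})")
    n_sig_pe = int((pe["p"] < 0.05).sum())
    n_sig_pg = int((pg["p"] < 0.05).sum())
    print(f"families significant at 0.05: Pearson {n_sig_pe}, PGLS {n_sig_pg} "
          f"(of {len(pe) - 1} families + total)")
    print("note: phylogenetic correction typically weakens correlations driven "
          "by a single clade-level shift, which is the biological point")


if __name__ == "__main__":
    main()
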