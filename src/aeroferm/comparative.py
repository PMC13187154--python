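"""Gene-family copy number vs trait correlation, with phylogenetic correction.

Species trait values are not independent observations: close relatives share
most of their evolutionary history, and a trait evolving by Brownian motion on
the phylogeny has covariance proportional to the shared root-to-ancestor branch
length between each pair of tips.  Phylogenetic generalized least squares
(PGLS) fits the regression

    y = X beta + eps,   eps ~ N(0, sigma^2 * C_lambda)

where C is the Brownian-motion covariance matrix implied by the tree and
Pagel's lambda scales its off-diagonal entries (lambda = 0 recovers a star
phylogeny and ordinary least squares; lambda = 1 is pure Brownian motion).
Alongside PGLS, plain Pearson correlations per gene family are provided for
comparison, since the contrast between the two is the biological point:
apparent copy-number/trait correlations can be driven by a single duplication
event (e.g. a whole-genome duplication) inherited by one clade.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def normalize_label(name: str) -> str:
    """Fold case, whitespace and underscores so tree/table names can be matched."""
    return "_".join(str(name).strip().lower().replace("_", " ").split())


def read_newick(text: str, fold_labels: bool = False) -> dendropy.Tree:
    """Parse a rooted Newick tree, requiring branch lengths and unique tips.

    ``fold_labels`` rewrites tip labels with :func:`normalize_label`; by default
    the original labels are preserved and matching is done lazily downstream.
    """
    if Path(str(text)).suffix in {".nwk", ".newick", ".tre", ".tree"} and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True, rooting="force-rooted"
        )
    except Exception as err:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        if edge.length < 0 or not math.isfinite(edge.length):
            raise ValueError(f"negative or non-finite branch length {edge.length}")
    if fold_labels:
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = normalize_label(leaf.taxon.label)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_overlap(tree: dendropy.Tree, species: Iterable[str]) -> dendropy.Tree:
    """Restrict the tree to tips present in ``species`` (normalized matching).

    Unary internal nodes created by the pruning are collapsed with their branch
    lengths summed, so patristic distances among the kept tips are unchanged.
    Species dropped on either side are logged.
    """
    wanted = {normalize_label(s) for s in species}
    keep = [l for l in tip_labels(tree) if normalize_label(l) in wanted]
    if not keep:
        raise ValueError("no overlap between tree tips and the requested species")
    dropped_tree = sorted(set(tip_labels(tree)) - set(keep))
    matched = {normalize_label(l) for l in keep}
    dropped_species = sorted(wanted - matched)
    if dropped_tree:
        logger.info("pruning drops %d tree tips: %s", len(dropped_tree), dropped_tree[:10])
    if dropped_species:
        logger.info("species absent from tree: %s", dropped_species[:10])
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    pruned.is_rooted = True
    return pruned


def bm_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix implied by a rooted tree.

    Entry (i, j) is the depth (root-to-node distance) of the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip distances.
    Returns the matrix together with the tip-label order of its rows.
    """
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length
        if node.parent_node is None:
            depth[node] = float(el or 0.0)
            continue
        if el is None:
            raise ValueError("tree has edges without branch lengths")
        if el < 0:
            raise ValueError(f"negative branch length {el}")
        depth[node] = depth[node.parent_node] + float(el)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            C[i, i] = depth[node]
            below[node] = [i]
        else:
            kids = [below[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
            below[node] = [i for k in kids for i in k]
    return C, labels


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PglsResult:
    """Simple (one-predictor) PGLS fit summary."""

    beta: float
    se: float
    t_stat: float
    df: int
    p_value: float
    r_signed: float
    lambda_used: float
    intercept: float
    sigma2: float
    log_likelihood: float


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _gls_core(y: np.ndarray, X: np.ndarray, Cl: np.ndarray):
    try:
        cf = cho_factor(Cl, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "lambda-transformed covariance is singular (e.g. duplicated zero-length "
            "tips); cannot fit PGLS"
        ) from err
    CiX = cho_solve(cf, X)
    Ciy = cho_solve(cf, y)
    XtCiX = X.T @ CiX
    beta = np.linalg.solve(XtCiX, X.T @ Ciy)
    e = y - X @ beta
    rss = float(e @ cho_solve(cf, e))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return cf, beta, rss, XtCiX, logdet


def _gls_loglik(n: int, rss: float, logdet: float) -> float:
    sigma2_ml = rss / n
    return -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdet + n)


def pgls_fit(
    y: Sequence[float],
    x: Sequence[float],
    C: np.ndarray,
    lam: float | str = 1.0,
) -> PglsResult:
    """Fit trait ``y`` on predictor ``x`` under error covariance sigma^2 C_lambda.

    ``lam`` is a fixed Pagel's lambda in [0, 1] or ``"ml"`` to profile the
    likelihood over a 0.01 grid followed by golden-section refinement.  The
    signed correlation ``r_signed`` is sign(beta) * sqrt(R^2) where R^2 is
    measured against the intercept-only GLS fit under the same covariance.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = np.asarray(C, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError(f"PGLS needs at least 4 taxa, got {n}")
    if x.shape != y.shape or C.shape != (n, n):
        raise ValueError("y, x and C dimensions do not agree")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    X = np.column_stack([np.ones(n), x])

    if lam == "ml":
        grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
        lls = []
        for g in grid:
            try:
                _, _, rss, _, logdet = _gls_core(y, X, _lambda_transform(C, g))
                lls.append(_gls_loglik(n, rss, logdet))
            except ValueError:
                lls.append(-np.inf)
        k = int(np.argmax(lls))
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]

        def negll(g: float) -> float:
            try:
                _, _, rss, _, logdet = _gls_core(y, X, _lambda_transform(C, g))
            except ValueError:
                return np.inf
            return -_gls_loglik(n, rss, logdet)

        from scipy.optimize import minimize_scalar

        lam_val = float(grid[k])
        if lo < hi:
            res = minimize_scalar(negll, bounds=(lo, hi), method="bounded")
            if res.success and negll(float(res.x)) <= -lls[k]:
                lam_val = float(np.clip(res.x, 0.0, 1.0))
    else:
        lam_val = float(lam)
        if not 0.0 <= lam_val <= 1.0:
            raise ValueError("lambda must be in [0, 1]")

    Cl = _lambda_transform(C, lam_val)
    cf, beta, rss, XtCiX, logdet = _gls_core(y, X, Cl)
    df = n - 2
    sigma2 = rss / df
    cov_beta = sigma2 * np.linalg.inv(XtCiX)
    se = float(np.sqrt(cov_beta[1, 1]))
    t_stat = float(beta[1] / se)
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    # intercept-only GLS fit for R^2
    ones = np.ones((n, 1))
    Ci1 = cho_solve(cf, ones)
    mu = float(((ones.T @ cho_solve(cf, y)) / (ones.T @ Ci1)).item())
    e0 = y - mu
    rss0 = float(e0 @ cho_solve(cf, e0))
    r2 = 0.0 if rss0 == 0 else max(0.0, min(1.0, 1.0 - rss / rss0))
    r_signed = float(np.sign(beta[1]) * np.sqrt(r2))
    return PglsResult(
        beta=float(beta[1]),
        se=se,
        t_stat=t_stat,
        df=df,
        p_value=p,
        r_signed=r_signed,
        lambda_used=lam_val,
        intercept=float(beta[0]),
        sigma2=float(sigma2),
        log_likelihood=_gls_loglik(n, rss, logdet),
    )


# ---------------------------------------------------------------------------
# per-family tables
# ---------------------------------------------------------------------------

STAR_THRESHOLDS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return ""


def _family_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c not in {"species", "order", "total"}]


def with_total(counts: pd.DataFrame) -> pd.DataFrame:
    """Append/refresh the ``total`` column = row sum over gene-family columns."""
    counts = counts.copy()
    fams = _family_columns(counts)
    counts["total"] = counts[fams].sum(axis=1)
    return counts


def _align(trait: pd.DataFrame, counts: pd.DataFrame, subset: Iterable[str] | None):
    t = trait.copy()
    c = with_total(counts)
    t["_key"] = t["species"].map(normalize_label)
    c["_key"] = c["species"].map(normalize_label)
    merged = t.merge(c, on="_key", suffixes=("_trait", ""))
    if subset is not None:
        wanted = {normalize_label(s) for s in subset}
        merged = merged[merged["_key"].isin(wanted)]
    unmatched = set(t["_key"]) - set(merged["_key"])
    if unmatched:
        logger.info("species without count data dropped: %s", sorted(unmatched)[:10])
    return merged


def pearson_by_family(
    trait: pd.DataFrame,
    counts: pd.DataFrame,
    subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of mean ECAR with each family's copy number.

    ``trait`` has columns species, mean_ecar; ``counts`` has a species column
    plus one integer column per gene family (an ``order`` column, if present,
    is ignored here but usable through ``subset``).  The ``total`` row sum is
    always included as its own entry.  Families with zero count variance yield
    missing correlations with a logged reason, never r = 0.
    """
    merged = _align(trait, counts, subset)
    rows = []
    for fam in _family_columns(counts) + ["total"]:
        sub = merged[["mean_ecar", fam]].dropna()
        n = len(sub)
        if n < 3:
            rows.append({"family": fam, "n": n, "r": np.nan, "p": np.nan,
                         "stars": "", "note": "fewer than 3 species"})
            continue
        xv = sub[fam].to_numpy(dtype=float)
        yv = sub["mean_ecar"].to_numpy(dtype=float)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            logger.info("family %s has zero variance; correlation undefined", fam)
            rows.append({"family": fam, "n": n, "r": np.nan, "p": np.nan,
                         "stars": "", "note": "zero variance"})
            continue
        r, p = stats.pearsonr(xv, yv)
        rows.append({"family": fam, "n": n, "r": float(r), "p": float(p),
                     "stars": significance_stars(p), "note": ""})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def pgls_by_family(
    trait: pd.DataFrame,
    counts: pd.DataFrame,
    tree: dendropy.Tree,
    lam: float | str = 1.0,
    subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """PGLS of mean ECAR on copy number, one fit per family plus the total.

    The tree is pruned to the species shared by all three inputs (restricted to
    ``subset`` when given).  Families whose fit fails (zero variance, singular
    covariance) are reported with a note rather than aborting the table.
    """
    merged = _align(trait, counts, subset)
    pruned = prune_to_overlap(tree, merged["_key"])
    C, labels = bm_covariance(pruned)
    key_order = [normalize_label(l) for l in labels]
    merged = merged.set_index("_key").loc[key_order]
    y = merged["mean_ecar"].to_numpy(dtype=float)
    rows = []
    for fam in _family_columns(counts) + ["total"]:
        xv = merged[fam].to_numpy(dtype=float)
        try:
            fit = pgls_fit(y, xv, C, lam=lam)
        except ValueError as err:
            logger.info("family %s: PGLS failed (%s)", fam, err)
            rows.append({"family": fam, "n": len(y), "beta": np.nan, "se": np.nan,
                         "t": np.nan, "df": len(y) - 2, "p": np.nan,
                         "r_signed": np.nan, "lambda": np.nan, "stars": "",
                         "note": str(err)})
            continue
        rows.append({"family": fam, "n": len(y), "beta": fit.beta, "se": fit.se,
                     "t": fit.t_stat, "df": fit.df, "p": fit.p_value,
                     "r_signed": fit.r_signed, "lambda": fit.lambda_used,
                     "stars": significance_stars(fit.p_value), "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"species", "mean_ecar"}.issubset(df.columns):
        raise ValueError(f"{path}: trait table needs columns species, mean_ecar")
    return df


def read_counts_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    df = df.rename(columns={df.columns[0]: "species"} if "species" not in df.columns else {})
    if "species" not in df.columns:
        raise ValueError(f"{path}: counts table needs a species column")
    return df
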