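"""Proteome ratio aggregation, translation-efficiency fold changes and the
codon-composition PLSR.

Protein-level changes come from metabolic-labeling MS: each protein's
peptide-level 14N/15N ratios are averaged as a geometric mean with a
geometric-SD quality filter, replicates are kept only when they agree in
direction, and the translation-efficiency (TE) fold change is the protein
fold change divided by the mRNA fold change.  Partial least squares
regression then relates each gene's 61-codon composition (X) to its
log10 TE fold change (y); on a correlation-loading plot the first component
separates optimal from non-optimal codons, with the response clustering with
the non-optimal side when pausing on optimal codons represses translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

TE_UP_CUTOFF = 1.5
TE_DOWN_CUTOFF = 0.67
PROTEIN_UP_CUTOFF = 1.5
PROTEIN_DOWN_CUTOFF = 0.67
MRNA_UP_CUTOFF = 2.0
MRNA_DOWN_CUTOFF = 0.5
SD_GEO_CUTOFF = 1000.0


# ---------------------------------------------------------------------------
# peptide ratio aggregation
# ---------------------------------------------------------------------------

@dataclass
class PeptideRatioSet:
    protein_id: str
    ratios: list[float]
    geometric_mean: float
    sd_geo: float
    pass_filter: bool


def aggregate_protein_ratio(protein_id: str, ratios: Sequence[float]) -> PeptideRatioSet:
    """Geometric mean and geometric SD of a protein's peptide ratios.

    A singleton set has sd_geo 1 by convention.  Proteins with
    sd_geo >= 1000 fail the quality filter.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("no peptide ratios")
    if (arr <= 0).any():
        raise ValueError("peptide ratios must be positive")
    gm = float(stats.gmean(arr))
    sd = 1.0 if arr.size == 1 else float(stats.gstd(arr))
    return PeptideRatioSet(protein_id, list(map(float, arr)), gm, sd, sd < SD_GEO_CUTOFF)


def aggregate_peptide_table(peptides: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a (protein_id, peptide_id, ratio) table to per-protein stats."""
    rows = []
    for pid, grp in peptides.groupby("protein_id"):
        r = aggregate_protein_ratio(str(pid), grp["ratio"].to_numpy())
        rows.append(
            {
                "protein_id": pid,
                "n_peptides": len(r.ratios),
                "geometric_mean": r.geometric_mean,
                "sd_geo": r.sd_geo,
                "pass_filter": r.pass_filter,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def concordance_filter(
    replicate_a: pd.Series, replicate_b: pd.Series, average: str = "geometric"
) -> pd.DataFrame:
    """Keep proteins whose fold changes agree in direction across replicates.

    Concordance means both replicates are on the same side of 1
    (log(a) * log(b) > 0); a replicate exactly at 1 is unchanged and drops
    the protein.  The combined value is the geometric (default) or
    arithmetic mean of the two replicates.  Symmetric in its arguments.
    """
    shared = replicate_a.index.intersection(replicate_b.index)
    a, b = replicate_a[shared].astype(float), replicate_b[shared].astype(float)
    keep = np.log(a) * np.log(b) > 0
    if average == "geometric":
        combined = np.sqrt(a[keep] * b[keep])
    elif average == "arithmetic":
        combined = (a[keep] + b[keep]) / 2
    else:
        raise ValueError(f"unknown average {average!r}")
    return pd.DataFrame({"fold_change": combined})


# ---------------------------------------------------------------------------
# TE fold change and classification
# ---------------------------------------------------------------------------

def _classify(fc: float, up: float, down: float) -> str:
    if np.isnan(fc):
        return "undefined"
    if fc > up:
        return "up"
    if fc < down:
        return "down"
    return "unchanged"


@dataclass
class TEChangeRecord:
    gene_id: str
    protein_fc: float
    mrna_fc: float
    te_fc: float
    te_class: str
    protein_class: str
    mrna_class: str


def te_fold_change(gene_id: str, protein_fc: float, mrna_fc: float) -> TEChangeRecord:
    """TE fold change = protein fold change / mRNA fold change, with classes.

    TE and protein classes use 1.5/0.67 cutoffs, mRNA 2/0.5; all strict.
    """
    if mrna_fc <= 0:
        raise ValueError("mRNA fold change must be positive")
    te = protein_fc / mrna_fc
    return TEChangeRecord(
        gene_id=gene_id,
        protein_fc=protein_fc,
        mrna_fc=mrna_fc,
        te_fc=te,
        te_class=_classify(te, TE_UP_CUTOFF, TE_DOWN_CUTOFF),
        protein_class=_classify(protein_fc, PROTEIN_UP_CUTOFF, PROTEIN_DOWN_CUTOFF),
        mrna_class=_classify(mrna_fc, MRNA_UP_CUTOFF, MRNA_DOWN_CUTOFF),
    )


def te_table(protein_fc: pd.Series, mrna_fc: pd.Series) -> pd.DataFrame:
    genes = protein_fc.index.intersection(mrna_fc.index)
    recs = [te_fold_change(str(g), float(protein_fc[g]), float(mrna_fc[g])) for g in genes]
    return pd.DataFrame(
        {
            "protein_fc": [r.protein_fc for r in recs],
            "mrna_fc": [r.mrna_fc for r in recs],
            "te_fc": [r.te_fc for r in recs],
            "te_class": [r.te_class for r in recs],
            "protein_class": [r.protein_class for r in recs],
            "mrna_class": [r.mrna_class for r in recs],
        },
        index=genes,
    )


# ---------------------------------------------------------------------------
# bin and window summaries
# ---------------------------------------------------------------------------

def cbi_bin_summary(
    classes: pd.Series, cbi_values: pd.Series, n_bins: int = 7, binning: str = "width"
) -> pd.DataFrame:
    """Fraction of up/down/unchanged genes per CBI bin.

    Bins are equal-width CBI intervals by default (gene numbers per bin may
    be uneven); 'quantile' gives equal-count bins.  Empty bins have NaN
    fractions.  Returns one row per bin with bin_center, n_genes and a
    fraction column per class.
    """
    genes = classes.index.intersection(cbi_values.index)
    cls, cbi = classes[genes], cbi_values[genes].astype(float)
    if binning == "width":
        bins = pd.cut(cbi, n_bins)
    elif binning == "quantile":
        bins = pd.qcut(cbi, n_bins, duplicates="drop")
    else:
        raise ValueError(f"unknown binning {binning!r}")
    labels = sorted(cls.unique())
    rows = []
    for interval, grp in cls.groupby(bins, observed=False):
        row = {"bin_center": interval.mid, "n_genes": len(grp)}
        for lab in labels:
            row[f"frac_{lab}"] = (grp == lab).mean() if len(grp) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def sliding_window_fraction(
    classes: pd.Series, ranking_values: pd.Series, window_size: int = 100
) -> pd.DataFrame:
    """Class fractions in overlapping windows along a gene ranking.

    Genes are ranked by ``ranking_values`` (ascending, e.g. ADAT-NNC codon
    content); a window of ``window_size`` genes slides one gene at a time and
    the fraction of each class inside the window is recorded.  Fractions in
    each window sum to 1.
    """
    genes = classes.index.intersection(ranking_values.index)
    order = ranking_values[genes].sort_values(kind="mergesort").index
    cls = classes[order].to_numpy()
    if len(cls) < window_size:
        raise ValueError("fewer genes than window size")
    labels = sorted(set(cls))
    onehot = {lab: (cls == lab).astype(float) for lab in labels}
    kernel = np.ones(window_size) / window_size
    rows = {"window_center_rank": np.arange(len(cls) - window_size + 1) + (window_size + 1) / 2}
    rows["mean_ranking_value"] = np.convolve(
        ranking_values[order].to_numpy(float), kernel, mode="valid"
    )
    for lab in labels:
        rows[f"frac_{lab}"] = np.convolve(onehot[lab], kernel, mode="valid")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PLSR of codon composition against TE change
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """Fitted PLSR with the quantities needed for a correlation-loading plot."""

    n_components: int
    variables: list[str]
    x_scores: np.ndarray              # genes x components
    x_loadings: np.ndarray            # variables x components
    y_loadings: np.ndarray            # 1 x components
    explained_x_variance: np.ndarray  # per component, fraction of X SS
    explained_y_variance: np.ndarray  # cumulative R^2 of y after k components
    correlation_loadings: pd.DataFrame  # variables + 'y' rows x component columns
    loo_predictions: np.ndarray
    dropped_variables: list[str]
    collinear_pairs: pd.DataFrame     # variable pairs with |r| > 0.8

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._estimator.predict(np.asarray(X, float)).ravel()


def codon_composition_matrix(codon_counts: pd.DataFrame, composition: bool = True) -> pd.DataFrame:
    """Genes x 61 codon-content matrix (counts over gene total by default)."""
    X = codon_counts.astype(float)
    if composition:
        X = X.div(X.sum(axis=1), axis=0)
    return X


def plsr_fit(
    X: pd.DataFrame,
    y: pd.Series,
    n_components: int = 2,
    standardize: bool = True,
    collinearity_cutoff: float = 0.8,
) -> PLSRModel:
    """NIPALS partial least squares of y on X with LOO cross-validation.

    Correlation loadings are the Pearson correlations of each X variable
    (and of y) with each component's scores, so they live in the unit disk;
    the 50% and 100% explained-variance circles of the standard plot are at
    radius sqrt(0.5) and 1.  Zero-variance columns are dropped with a record.
    LOO predictions refit the model on n-1 genes for each gene.
    """
    X = X.copy().astype(float)
    y = y.loc[X.index].astype(float)
    n = len(X)
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 genes")
    variances = X.var(axis=0, ddof=0)
    dropped = list(X.columns[variances == 0])
    X = X.drop(columns=dropped)

    est = PLSRegression(n_components=n_components, scale=standardize)
    est.fit(X.to_numpy(), y.to_numpy())
    T = est.x_scores_
    P = est.x_loadings_

    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    if standardize:
        Xc = Xc / X.to_numpy().std(axis=0, ddof=1)
    total_x_ss = (Xc ** 2).sum()
    expl_x = np.array(
        [(np.outer(T[:, k], P[:, k]) ** 2).sum() / total_x_ss for k in range(n_components)]
    )

    yc = y.to_numpy() - y.mean()
    total_y_ss = (yc ** 2).sum()
    expl_y = np.empty(n_components)
    for k in range(1, n_components + 1):
        coef, *_ = np.linalg.lstsq(T[:, :k], yc, rcond=None)
        expl_y[k - 1] = 1 - ((yc - T[:, :k] @ coef) ** 2).sum() / total_y_ss

    corr = {}
    for k in range(n_components):
        t = T[:, k]
        col = [stats.pearsonr(X[v].to_numpy(), t).statistic for v in X.columns]
        col.append(stats.pearsonr(y.to_numpy(), t).statistic)
        corr[f"component_{k + 1}"] = col
    corr_df = pd.DataFrame(corr, index=list(X.columns) + ["y"])

    loo = np.empty(n)
    Xa, ya = X.to_numpy(), y.to_numpy()
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        e = PLSRegression(n_components=n_components, scale=standardize)
        e.fit(Xa[mask], ya[mask])
        loo[i] = e.predict(Xa[i:i + 1]).ravel()[0]

    cm = X.corr().abs()
    pairs = [
        {"var_a": a, "var_b": b, "abs_r": cm.loc[a, b]}
        for i, a in enumerate(cm.index)
        for b in cm.index[i + 1:]
        if cm.loc[a, b] > collinearity_cutoff
    ]
    collinear = pd.DataFrame(pairs, columns=["var_a", "var_b", "abs_r"])

    model = PLSRModel(
        n_components=n_components,
        variables=list(X.columns),
        x_scores=T,
        x_loadings=P,
        y_loadings=est.y_loadings_,
        explained_x_variance=expl_x,
        explained_y_variance=expl_y,
        correlation_loadings=corr_df,
        loo_predictions=loo,
        dropped_variables=dropped,
        collinear_pairs=collinear,
    )
    model._estimator = est
    return model
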