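"""Tissue expression profiles and a negative-binomial two-group test.

Profiles follow the survey convention of reporting, per gene, the maximum
TPM-scale abundance reached in each sample type, summarized by the tissue
specificity index tau (0 = uniform across types, 1 = confined to one type).

Differential expression between control and stimulated samples of an
experiment uses a self-contained negative-binomial Wald test: samples are
normalized by median-of-ratios size factors, the NB dispersion is estimated
by the method of moments within groups, and the log2 fold change is tested
against a normal reference. This is a deliberately simple stand-in for a
full shrinkage-based GLM framework; the biological decision threshold
(p < 0.05, on raw p by default) is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SAMPLE_TYPES, ExpressionDataset

__all__ = [
    "TissueProfile",
    "tissue_profile",
    "tissue_profiles",
    "tau_index",
    "size_factors",
    "nb_two_group_test",
    "modulate_experiment",
    "modulation_summary",
]

#: Floor for method-of-moments dispersion estimates.
MIN_DISPERSION = 1e-8

#: Pseudocount added to normalized group means in fold changes, keeping
#: fold changes finite for genes silent in one group.
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class TissueProfile:
    gene_id: str
    max_abundance: Mapping[str, float]  # sample_type → max TPM
    tau: float


def tau_index(maxima: Sequence[float]) -> float:
    """Tissue-specificity index over per-type expression maxima.

    tau = Σᵢ (1 − xᵢ/max(x)) / (n − 1); 0 for uniform expression, 1 for
    expression confined to a single type, 0 by convention if all zero.
    """
    x = np.asarray(maxima, dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression value")
    if x.size < 2:
        return 0.0
    top = x.max()
    if top == 0:
        return 0.0
    return float(np.sum(1.0 - x / top) / (x.size - 1))


def tissue_profile(
    ds: ExpressionDataset,
    gene: str,
    sample_types: Sequence[str] | None = None,
) -> TissueProfile:
    """Per-sample-type abundance maxima and tau for one gene.

    ``sample_types`` defaults to the types present in the metadata, in
    canonical order.
    """
    if gene not in ds.abundance.index:
        raise KeyError(f"unknown gene {gene!r}")
    if sample_types is None:
        seen = set(ds.sample_meta["sample_type"])
        sample_types = [t for t in SAMPLE_TYPES if t in seen]
    maxima: dict[str, float] = {}
    for st in sample_types:
        samples = ds.samples_where(sample_type=st)
        if not samples:
            raise ValueError(f"no samples of type {st!r}")
        maxima[st] = float(ds.abundance.loc[gene, samples].max())
    return TissueProfile(
        gene_id=gene,
        max_abundance=maxima,
        tau=tau_index(list(maxima.values())),
    )


def tissue_profiles(
    ds: ExpressionDataset, sample_types: Sequence[str] | None = None
) -> pd.DataFrame:
    """Vectorized profile table for all genes: one max column per sample
    type plus a ``tau`` column."""
    if sample_types is None:
        seen = set(ds.sample_meta["sample_type"])
        sample_types = [t for t in SAMPLE_TYPES if t in seen]
    maxima = pd.DataFrame(index=ds.abundance.index)
    for st in sample_types:
        samples = ds.samples_where(sample_type=st)
        if not samples:
            raise ValueError(f"no samples of type {st!r}")
        maxima[st] = ds.abundance[samples].max(axis=1)
    x = maxima.to_numpy(dtype=float)
    top = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(
            top > 0, (1.0 - x / top[:, None]).sum(axis=1) / (n - 1), 0.0
        )
    out = maxima.copy()
    out["tau"] = tau
    out.index.name = "gene_id"
    return out


def size_factors(
    counts: pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean rescaled to 1.

    The reference profile is the per-gene geometric mean across samples,
    computed over genes with nonzero counts in every sample; each sample's
    factor is the median ratio of its counts to the reference. With
    ``pseudo_reference=True`` the geometric mean is taken over positive
    counts only (for sparse data without an all-positive gene), and ratios
    are taken at positive counts.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = counts.to_numpy(dtype=float)
    if not pseudo_reference:
        all_positive = (vals > 0).all(axis=1)
        if not all_positive.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        sub = vals[all_positive]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / ref[:, None]
        factors = np.median(ratios, axis=0)
    else:
        positive = vals > 0
        usable = positive.any(axis=1)
        sub = vals[usable]
        pos = positive[usable]
        logs = np.zeros_like(sub)
        np.log(sub, out=logs, where=pos)
        ref = np.exp(logs.sum(axis=1) / pos.sum(axis=1))
        factors = np.empty(vals.shape[1])
        for j in range(vals.shape[1]):
            mask = pos[:, j]
            if not mask.any():
                raise ValueError(
                    f"sample {counts.columns[j]!r} has an all-zero library"
                )
            factors[j] = np.median(sub[mask, j] / ref[mask])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, group_idx: Sequence[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion pooled across groups by method of moments.

    Within each group g, alpha_g solves var = mu + alpha mu^2 on the
    normalized counts; group estimates are pooled with (n_g − 1) weights
    and floored at MIN_DISPERSION.
    """
    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in group_idx:
        sub = norm[:, idx]
        n_g = sub.shape[1]
        if n_g < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += (n_g - 1) * a
        den += n_g - 1
    alpha = num / den if den else np.zeros(norm.shape[0])
    return np.maximum(alpha, MIN_DISPERSION)


def nb_two_group_test(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    groups: Mapping[str, str] | pd.Series | None = None,
    alpha: float = 0.05,
    use_bh: bool = False,
) -> pd.DataFrame:
    """Per-gene NB Wald test of stimulated vs control samples.

    ``groups`` maps each sample column to ``"control"`` or
    ``"stimulated"`` (≥2 samples each). Returns a DataFrame indexed by gene
    with columns log2fc, se, wald_p, bh_q, significant. The significance
    call uses raw p (or BH q with ``use_bh=True``) against ``alpha``.
    """
    if groups is None:
        raise ValueError("groups mapping is required")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = set(groups)
    if not labels <= {"control", "stimulated"}:
        raise ValueError(f"unknown group labels: {sorted(labels - {'control', 'stimulated'})}")
    ctrl = [s for s in counts.columns if groups.get(s) == "control"]
    stim = [s for s in counts.columns if groups.get(s) == "stimulated"]
    if len(ctrl) < 2 or len(stim) < 2:
        raise ValueError("need at least 2 samples per group")
    sub = counts[ctrl + stim]
    if (sub.sum(axis=0) == 0).any():
        dead = sub.columns[sub.sum(axis=0) == 0]
        raise ValueError(f"all-zero library: {list(dead)}")
    if factors is None:
        factors = size_factors(sub)
    sf = factors.loc[ctrl + stim].to_numpy(dtype=float)
    norm = sub.to_numpy(dtype=float) / sf
    idx_c = np.arange(len(ctrl))
    idx_s = np.arange(len(ctrl), len(ctrl) + len(stim))

    mu_c = norm[:, idx_c].mean(axis=1)
    mu_s = norm[:, idx_s].mean(axis=1)
    log2fc = np.log2((mu_s + PSEUDOCOUNT) / (mu_c + PSEUDOCOUNT))
    disp = _mom_dispersion(norm, [idx_c, idx_s])

    ln2_sq = np.log(2.0) ** 2

    def _var_log2(mu: np.ndarray, idx: np.ndarray) -> np.ndarray:
        # Delta-method variance of log2(mu_hat + pseudocount); the NB
        # variance mu*s + alpha*(mu*s)^2 of each raw count propagates
        # through the size factors and the group mean.
        mu_eff = mu + PSEUDOCOUNT
        inv_s = np.sum(1.0 / sf[idx])
        n = idx.size
        var_mu = mu_eff * inv_s / n**2 + disp * np.square(mu_eff) / n
        return var_mu / (np.square(mu_eff) * ln2_sq)

    se = np.sqrt(_var_log2(mu_c, idx_c) + _var_log2(mu_s, idx_s))
    z = log2fc / se
    # t reference with n1+n2-2 df: the plug-in dispersion makes a plain
    # normal reference anticonservative at typical replicate numbers.
    dof = len(ctrl) + len(stim) - 2
    wald_p = 2.0 * stats.t.sf(np.abs(z), dof)
    bh_q = multipletests(wald_p, method="fdr_bh")[1]
    selected = bh_q if use_bh else wald_p
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "wald_p": wald_p,
            "bh_q": bh_q,
            "significant": selected < alpha,
        },
        index=sub.index,
    )
    out.index.name = "gene_id"
    return out


def modulate_experiment(
    ds: ExpressionDataset,
    experiment_id: str,
    alpha: float = 0.05,
    use_bh: bool = False,
) -> pd.DataFrame:
    """Run the NB test on one experiment's control vs stimulated samples.

    Size factors are computed on the experiment's samples only. The result
    carries an ``experiment_id`` column for downstream stacking.
    """
    samples = ds.samples_where(experiment_id=experiment_id)
    if not samples:
        raise ValueError(f"unknown experiment {experiment_id!r}")
    meta = ds.sample_meta.set_index("sample_id")
    groups = meta.loc[samples, "condition"]
    res = nb_two_group_test(
        ds.counts[samples], groups=groups, alpha=alpha, use_bh=use_bh
    )
    res.insert(0, "experiment_id", experiment_id)
    return res


def modulation_summary(
    results: pd.DataFrame,
    gene_strata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Stacked up/down counts of significant genes per experiment.

    ``results`` concatenates outputs of :func:`modulate_experiment`.
    ``gene_strata`` optionally maps genes to a stratum label (e.g. a
    conservation level or subfamily); unmapped genes fall in
    ``"unassigned"``. Returns rows (experiment_id, stratum, n_up, n_down);
    empty input yields an empty frame.
    """
    cols = ["experiment_id", "stratum", "n_up", "n_down"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    sig = results.loc[results["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(columns=cols)
    if gene_strata is None:
        sig["stratum"] = "all"
    else:
        sig["stratum"] = [gene_strata.get(g, "unassigned") for g in sig.index]
    sig["direction"] = np.where(sig["log2fc"] > 0, "n_up", "n_down")
    tab = (
        sig.groupby(["experiment_id", "stratum", "direction"])
        .size()
        .unstack("direction", fill_value=0)
        .reindex(columns=["n_up", "n_down"], fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    return tab[cols]
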