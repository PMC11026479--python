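"""Activity scoring and functional-variant calling.

Per allele, the activity score is A = C_RNA / C_DNA on quantile-normalized,
replicate-summed UMI counts; the variant effect size is the relative activity
lnFC = ln(A_alt / A_ref).  Allelic differences are tested with a negative
binomial model of RNA counts with the log DNA count as offset: the
likelihood-ratio statistic for the allele term is referred to chi-square with
1 df.  Dispersion is a single per-dataset parameter shared across variants
(three replicates per allele are too few for stable per-variant estimates),
obtained by profile maximum likelihood with a method-of-moments fallback.

A variant is called functional when its Benjamini-Hochberg FDR is <= 0.10 and
|lnFC| >= 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

PSEUDOCOUNT = 0.5        # display-only guard against zero counts in lnFC
DEFAULT_MIN_DNA = 10     # min deduplicated DNA families per allele (summed)
DEFAULT_FDR_CUT = 0.10
DEFAULT_EFFECT_CUT = 0.10


def _attach_design(df: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Join (variant_id, allele) onto a counts-like frame via oligo_id."""
    df = df.drop(columns=[c for c in ("variant_id", "allele") if c in df])
    return df.merge(
        design[["oligo_id", "variant_id", "allele"]], on="oligo_id", how="inner"
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(counts: pd.DataFrame, value_col: str = "dedup") -> pd.DataFrame:
    """Classic rank-mean quantile normalization across replicates.

    Applied separately within each library type; ties receive the mean of the
    tied target values.  Input/output are tidy frames (oligo_id, replicate,
    library_type, value); the normalized column is named ``norm``.
    """
    out = []
    for lib, grp in counts.groupby("library_type"):
        wide = grp.pivot(index="oligo_id", columns="replicate", values=value_col)
        wide = wide.fillna(0.0)
        if wide.shape[1] < 2:
            raise ValueError("quantile normalization requires >= 2 replicates")
        if (wide.sum(axis=0) == 0).any():
            raise ValueError(f"{lib}: a replicate has all-zero counts")
        arr = wide.to_numpy(dtype=float)
        target = np.sort(arr, axis=0).mean(axis=1)
        normed = np.empty_like(arr)
        for j in range(arr.shape[1]):
            ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties avg
            lo = np.floor(ranks).astype(int) - 1
            hi = np.ceil(ranks).astype(int) - 1
            normed[:, j] = (target[lo] + target[hi]) / 2.0
        wide = pd.DataFrame(normed, index=wide.index, columns=wide.columns)
        tidy = wide.reset_index().melt(
            id_vars="oligo_id", var_name="replicate", value_name="norm"
        )
        tidy["library_type"] = lib
        out.append(tidy)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# activity scores
# ---------------------------------------------------------------------------

def activity_score(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    raw_counts: pd.DataFrame | None = None,
    min_dna: float = DEFAULT_MIN_DNA,
) -> pd.DataFrame:
    """Per-allele activity A = C_RNA / C_DNA on replicate-summed counts.

    Alleles whose raw deduplicated DNA total falls below ``min_dna`` are
    flagged ``low_coverage`` and excluded from downstream testing.
    """
    merged = _attach_design(norm, design)
    summed = (
        merged.groupby(["variant_id", "allele", "library_type"])["norm"]
        .sum()
        .unstack("library_type")
        .reindex(columns=["DNA", "RNA"])
        .reset_index()
        .rename(columns={"DNA": "c_dna", "RNA": "c_rna"})
    )
    if raw_counts is not None:
        raw = _attach_design(raw_counts, design)
        raw_dna = (
            raw[raw.library_type == "DNA"]
            .groupby(["variant_id", "allele"])["dedup"].sum()
            .rename("raw_dna")
            .reset_index()
        )
        summed = summed.merge(raw_dna, on=["variant_id", "allele"], how="left")
        summed["raw_dna"] = summed["raw_dna"].fillna(0)
    else:
        summed["raw_dna"] = summed["c_dna"]
    summed["low_coverage"] = summed["raw_dna"] < min_dna
    with np.errstate(divide="ignore", invalid="ignore"):
        summed["activity"] = np.where(
            summed["c_dna"] > 0, summed["c_rna"] / summed["c_dna"], np.nan
        )
    return summed


def relative_activity(a_ref: float, a_alt: float) -> float:
    """lnFC = ln(A_alt / A_ref); infinite when one activity is zero."""
    if a_ref == 0 and a_alt == 0:
        return np.nan
    if a_ref == 0:
        return np.inf
    if a_alt == 0:
        return -np.inf
    return float(np.log(a_alt / a_ref))


# ---------------------------------------------------------------------------
# negative binomial likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= 1e-12:
        return float(stats.poisson.logpmf(y, mu).sum())
    n = 1.0 / alpha
    p = n / (n + mu)
    return float(stats.nbinom.logpmf(y, n, p).sum())


def _fit_rate(y: np.ndarray, d: np.ndarray, alpha: float) -> tuple[float, float]:
    """MLE of the common rate r in RNA ~ NB(mean = r * DNA); returns
    (rate, loglik).  The Poisson MLE sum(y)/sum(d) seeds a 1-D search."""
    r0 = max(y.sum() / max(d.sum(), 1e-12), 1e-12)
    if alpha <= 1e-12:
        return r0, _nb_loglik(y, r0 * d, alpha)

    def neg(logr):
        return -_nb_loglik(y, np.exp(logr) * d, alpha)

    res = optimize.minimize_scalar(
        neg, bracket=(np.log(r0) - 0.5, np.log(r0), np.log(r0) + 0.5)
        if r0 > 1e-11 else None,
        bounds=(np.log(r0) - 5, np.log(r0) + 5), method="bounded",
    )
    r = float(np.exp(res.x))
    return r, -float(res.fun)


def estimate_dispersion(
    dna: np.ndarray, rna: np.ndarray, groups: np.ndarray,
    method: str = "mle", max_groups: int = 200,
) -> float:
    """Shared NB dispersion alpha across allele groups.

    ``dna``/``rna`` are flat count arrays and ``groups`` labels observations
    belonging to the same (variant, allele).  ``mle`` maximises a Cox-Reid
    adjusted profile likelihood for a common alpha (group rates re-fit at
    each alpha, minus half the log Fisher information of each fitted rate);
    the adjustment counters the downward Neyman-Scott bias from estimating
    one nuisance rate per few-replicate group.  At most ``max_groups`` groups
    enter the profile.  ``moments`` uses pooled squared residuals with a
    (R-1)/R degrees-of-freedom correction, which is also the fallback when
    the profile likelihood is degenerate.
    """
    dna = np.asarray(dna, float)
    rna = np.asarray(rna, float)
    uniq = pd.unique(groups)
    # method of moments with a df correction for the fitted group rate:
    # E[sum (y - mu_hat)^2] ~= (R-1)/R * sum(mu + alpha mu^2)
    num = den = 0.0
    for g in uniq:
        m = groups == g
        d, y = dna[m], rna[m]
        R = len(y)
        if d.sum() <= 0 or R < 2:
            continue
        mu = y.sum() / d.sum() * d
        ss = float(((y - mu) ** 2).sum())
        num += ss * R / (R - 1) - float(mu.sum())
        den += float((mu ** 2).sum())
    mom = max(num / den, 1e-8) if den > 0 else 1e-8
    if method == "moments":
        return mom

    rng = np.random.default_rng(0)
    if len(uniq) > max_groups:
        uniq = rng.choice(uniq, size=max_groups, replace=False)
    subsets = []
    for g in uniq:
        m = groups == g
        if dna[m].sum() > 0 and len(rna[m]) >= 2:
            subsets.append((rna[m], dna[m]))
    if not subsets:
        return mom

    def neg_profile(log_alpha):
        alpha = float(np.exp(log_alpha))
        ll = 0.0
        for y, d in subsets:
            r, l = _fit_rate(y, d, alpha)
            mu = r * d
            # Cox-Reid: subtract 0.5 log of the observed information of the
            # profiled log-rate, sum(mu / (1 + alpha mu)).
            info = float((mu / (1.0 + alpha * mu)).sum())
            ll += l - 0.5 * np.log(max(info, 1e-12))
        return -ll

    try:
        res = optimize.minimize_scalar(
            neg_profile, bounds=(np.log(1e-8), np.log(10.0)), method="bounded",
            options={"xatol": 0.05},
        )
        return float(np.exp(res.x))
    except Exception:
        return mom


def test_variant(
    dna_ref: np.ndarray, rna_ref: np.ndarray,
    dna_alt: np.ndarray, rna_alt: np.ndarray,
    alpha: float,
) -> tuple[float, float]:
    """Likelihood-ratio test of an allele effect on RNA given DNA.

    Full model fits separate RNA/DNA rates per allele; the null shares one
    rate.  Returns (LR statistic, two-sided p) with the statistic referred to
    chi-square(1).  Falls back to a Welch t-test on per-replicate log ratios
    if the NB fit degenerates (both alleles all-zero RNA).
    """
    dna_ref = np.asarray(dna_ref, float); rna_ref = np.asarray(rna_ref, float)
    dna_alt = np.asarray(dna_alt, float); rna_alt = np.asarray(rna_alt, float)
    if dna_ref.sum() <= 0 or dna_alt.sum() <= 0:
        raise ValueError("both alleles need positive DNA coverage")
    try:
        _, ll_ref = _fit_rate(rna_ref, dna_ref, alpha)
        _, ll_alt = _fit_rate(rna_alt, dna_alt, alpha)
        _, ll_null = _fit_rate(
            np.concatenate([rna_ref, rna_alt]),
            np.concatenate([dna_ref, dna_alt]),
            alpha,
        )
        stat = max(2.0 * (ll_ref + ll_alt - ll_null), 0.0)
        p = float(stats.chi2.sf(stat, df=1))
        return stat, p
    except (ValueError, FloatingPointError):
        la = np.log((rna_ref + PSEUDOCOUNT) / (dna_ref + PSEUDOCOUNT))
        lb = np.log((rna_alt + PSEUDOCOUNT) / (dna_alt + PSEUDOCOUNT))
        t, p = stats.ttest_ind(lb, la, equal_var=False)
        return float(t ** 2), float(p)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_functional(
    tests: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR_CUT,
    effect_cut: float = DEFAULT_EFFECT_CUT,
) -> pd.DataFrame:
    """BH-correct p-values across all tested variants and apply the joint
    FDR <= ``fdr_cut`` and |lnFC| >= ``effect_cut`` rule."""
    out = tests.copy()
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    out["functional"] = (out["fdr"] <= fdr_cut) & (out["lnFC"].abs() >= effect_cut)
    out["direction"] = np.where(out["lnFC"] > 0, "up", "down")
    return out


def quantify_screen(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_dna: float = DEFAULT_MIN_DNA,
    fdr_cut: float = DEFAULT_FDR_CUT,
    effect_cut: float = DEFAULT_EFFECT_CUT,
    dispersion: float | None = None,
    dispersion_method: str = "mle",
    cell_line: str = "",
) -> pd.DataFrame:
    """End-to-end: counts -> normalization -> activity -> NB LRT -> calls.

    ``counts`` is the tidy CountMatrix (oligo_id, replicate, library_type,
    dedup [, raw]).  Returns one VariantCall row per testable variant with
    A_ref, A_alt, lnFC, p, FDR, functional flag and direction.
    """
    norm = quantile_normalize(counts)
    act = activity_score(norm, design, raw_counts=counts, min_dna=min_dna)
    wide = act.pivot(index="variant_id", columns="allele",
                     values=["activity", "low_coverage", "c_dna", "c_rna"])

    merged = _attach_design(counts, design)
    piv = merged.pivot_table(
        index=["variant_id", "allele", "replicate"], columns="library_type",
        values="dedup", aggfunc="sum", fill_value=0,
    )

    # shared dispersion across all allele groups
    flat = piv.reset_index()
    group_labels = (flat["variant_id"].astype(str) + ":" + flat["allele"]).to_numpy()
    if dispersion is None:
        dispersion = estimate_dispersion(
            flat["DNA"].to_numpy(), flat["RNA"].to_numpy(), group_labels,
            method=dispersion_method,
        )

    rows = []
    for vid in wide.index:
        try:
            low = bool(wide.loc[vid, ("low_coverage", "ref")]) or bool(
                wide.loc[vid, ("low_coverage", "alt")]
            )
        except KeyError:
            continue
        a_ref = wide.loc[vid, ("activity", "ref")]
        a_alt = wide.loc[vid, ("activity", "alt")]
        if low or np.isnan(a_ref) or np.isnan(a_alt):
            continue
        if a_ref > 0 and a_alt > 0:
            lnfc = relative_activity(a_ref, a_alt)
            capped = False
        else:
            lnfc = float(np.log(
                (wide.loc[vid, ("c_rna", "alt")] + PSEUDOCOUNT)
                / (wide.loc[vid, ("c_dna", "alt")] + PSEUDOCOUNT)
                / ((wide.loc[vid, ("c_rna", "ref")] + PSEUDOCOUNT)
                   / (wide.loc[vid, ("c_dna", "ref")] + PSEUDOCOUNT))
            ))
            capped = True
        try:
            sub_ref = piv.loc[(vid, "ref")]
            sub_alt = piv.loc[(vid, "alt")]
        except KeyError:
            continue
        stat, p = test_variant(
            sub_ref["DNA"].to_numpy(), sub_ref["RNA"].to_numpy(),
            sub_alt["DNA"].to_numpy(), sub_alt["RNA"].to_numpy(),
            alpha=dispersion,
        )
        rows.append(
            {
                "variant_id": vid,
                "A_ref": float(a_ref),
                "A_alt": float(a_alt),
                "lnFC": lnfc,
                "lnFC_capped": capped,
                "statistic": stat,
                "p_value": p,
                "cell_line": cell_line,
            }
        )
    tests = pd.DataFrame(rows)
    calls = call_functional(tests, fdr_cut=fdr_cut, effect_cut=effect_cut)
    calls.attrs["dispersion"] = float(dispersion)
    return calls


# ---------------------------------------------------------------------------
# group comparisons and QC
# ---------------------------------------------------------------------------

def compare_groups(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided",
    absolute: bool = False,
) -> tuple[float, float]:
    """Wilcoxon rank-sum of two lnFC sets (optionally on magnitudes).

    The alternative is with respect to ``a``: ``greater`` means the values in
    ``a`` are shifted above those in ``b``.
    """
    a = np.abs(np.asarray(a, float)) if absolute else np.asarray(a, float)
    b = np.abs(np.asarray(b, float)) if absolute else np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def replicate_qc(norm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-replicate activity scores."""
    merged = _attach_design(norm, design)
    piv = merged.pivot_table(
        index=["variant_id", "allele"], columns=["library_type", "replicate"],
        values="norm",
    )
    reps = sorted({r for (_l, r) in piv.columns})
    rows = []
    for i, r1 in enumerate(reps):
        for r2 in reps[i + 1:]:
            with np.errstate(divide="ignore", invalid="ignore"):
                a1 = piv[("RNA", r1)] / piv[("DNA", r1)]
                a2 = piv[("RNA", r2)] / piv[("DNA", r2)]
            ok = a1.notna() & a2.notna() & np.isfinite(a1) & np.isfinite(a2)
            rho, p = stats.spearmanr(a1[ok], a2[ok])
            rows.append({"rep_a": r1, "rep_b": r2, "spearman_rho": float(rho),
                         "p_value": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided z-test comparing two functional-fraction proportions."""
    stat, p = proportions_ztest([k1, k2], [n1, n2])
    return float(stat), float(p)
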