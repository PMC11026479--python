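"""Permutation-based term enrichment with a sampling-and-normal-fit p-value.

The query is the gene set of the top-ranked variants (by |lnFC| across cell
lines).  For each term, its occurrence among query genes is compared with the
occurrences in many size-matched control gene sets drawn from the background
(optionally matched per query gene on length and GC content within +/-10%);
the upper-tail p comes from a normal fit to the control occurrences.
Significance requires FDR < 0.05 and occurrence >= 5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIG_FDR = 0.05
SIG_MIN_OCCURRENCE = 5


def load_term_map(pairs) -> dict[str, set[str]]:
    """gene -> set of term ids, from (gene, term) pairs or a 2-column frame."""
    if isinstance(pairs, pd.DataFrame):
        pairs = pairs.itertuples(index=False)
    tm: dict[str, set[str]] = {}
    for gene, term in pairs:
        tm.setdefault(gene, set()).add(term)
    return tm


def rank_top_variants(calls: pd.DataFrame, top_n: int = 500) -> pd.DataFrame:
    """Top ``top_n`` unique variants ranked by max |lnFC| across cell lines.

    Duplicate variants (tested in several cell lines) are counted once at
    their largest magnitude; ties break deterministically on variant id.
    Returns the selected variant table (with ``gene`` if present).
    """
    df = calls.copy()
    df["abs_lnfc"] = df["lnFC"].abs()
    agg = {"abs_lnfc": "max"}
    if "gene" in df:
        agg["gene"] = "first"
    uniq = df.groupby("variant_id", as_index=False).agg(agg)
    uniq = uniq.sort_values(["abs_lnfc", "variant_id"],
                            ascending=[False, True], kind="stable")
    return uniq.head(top_n).reset_index(drop=True)


def sample_controls(
    query_genes,
    background_genes,
    n_sets: int = 10_000,
    matching: str = "none",
    gene_metrics: pd.DataFrame | None = None,
    tolerance: float = 0.10,
    seed: int = 0,
) -> list[np.ndarray]:
    """Control gene sets, each the size of the query, drawn from the
    background with query genes excluded.

    ``matching='length_gc'`` samples, for each query gene, a background gene
    whose length and GC content are both within ``tolerance`` (relative) of
    the query gene's; when no background gene qualifies the tolerance is
    widened stepwise (x1.5).  Genes that required widening are recorded on
    ``sample_controls.widened`` after the call.
    """
    rng = np.random.default_rng(seed)
    query = list(dict.fromkeys(query_genes))
    bg = np.array([g for g in dict.fromkeys(background_genes) if g not in set(query)])
    if len(bg) < len(query):
        raise ValueError("background smaller than query after exclusion")

    widened: list[str] = []
    if matching == "none":
        sets = [rng.choice(bg, size=len(query), replace=False)
                for _ in range(n_sets)]
    elif matching == "length_gc":
        if gene_metrics is None:
            raise ValueError("length_gc matching requires gene_metrics")
        gm = gene_metrics.set_index("gene")
        pools = []
        for g in query:
            L, gc = gm.loc[g, "length"], gm.loc[g, "gc"]
            tol = tolerance
            while True:
                ok = gm.loc[gm.index.isin(bg)]
                match = ok[
                    (ok["length"].sub(L).abs() <= tol * L)
                    & (ok["gc"].sub(gc).abs() <= tol * gc)
                ]
                if len(match):
                    pools.append(match.index.to_numpy())
                    break
                tol *= 1.5
                widened.append(g)
                if tol > 10:
                    raise ValueError(f"no control match found for gene {g!r}")
        sets = []
        for _ in range(n_sets):
            sets.append(np.array([pool[rng.integers(len(pool))] for pool in pools]))
    else:
        raise ValueError(f"unknown matching mode {matching!r}")
    sample_controls.widened = widened
    return sets


def permutation_enrichment(
    query_genes,
    control_sets,
    term_map: dict[str, set[str]],
    fdr_cut: float = SIG_FDR,
    min_occurrence: int = SIG_MIN_OCCURRENCE,
) -> pd.DataFrame:
    """Normal-fit upper-tail enrichment p per term.

    For each term, k = number of query genes annotated with it; control
    occurrences across the sampled sets give (mu, sigma) and
    p = 1 - Phi((k - mu)/sigma).  If sigma = 0 the add-one empirical p
    (r+1)/(n+1) with r = #controls >= k is used.  Terms absent from both the
    query and every control set are dropped.  BH correction runs across
    terms; significance = FDR < ``fdr_cut`` and k >= ``min_occurrence``.
    """
    query = list(dict.fromkeys(query_genes))
    terms = sorted({t for ts in term_map.values() for t in ts})
    t_idx = {t: i for i, t in enumerate(terms)}

    def occurrences(genes) -> np.ndarray:
        occ = np.zeros(len(terms), dtype=int)
        for g in genes:
            for t in term_map.get(g, ()):
                occ[t_idx[t]] += 1
        return occ

    k = occurrences(query)
    ctrl = np.vstack([occurrences(s) for s in control_sets])
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=0)
    n_sets = len(control_sets)

    rows = []
    for i, t in enumerate(terms):
        if k[i] == 0 and ctrl[:, i].sum() == 0:
            continue
        if sd[i] > 0:
            p = float(stats.norm.sf((k[i] - mu[i]) / sd[i]))
        else:
            r = int((ctrl[:, i] >= k[i]).sum())
            p = (r + 1) / (n_sets + 1)
        rows.append({"term": t, "occurrence": int(k[i]), "null_mean": float(mu[i]),
                     "null_sd": float(sd[i]), "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = (df["fdr"] < fdr_cut) & (df["occurrence"] >= min_occurrence)
        df = df.sort_values(["p_value", "term"]).reset_index(drop=True)
    return df


def count_disease_representation(
    query_genes, disease_map: dict[str, set[str]], top_k: int = 10,
) -> pd.DataFrame:
    """Diseases ranked by the number of query genes annotated with them."""
    counts: dict[str, int] = {}
    for g in dict.fromkeys(query_genes):
        for d in disease_map.get(g, ()):
            counts[d] = counts.get(d, 0) + 1
    df = pd.DataFrame(
        [{"disease": d, "n_genes": n} for d, n in counts.items()],
        columns=["disease", "n_genes"],
    )
    if len(df):
        df = df.sort_values(["n_genes", "disease"],
                            ascending=[False, True]).reset_index(drop=True)
    return df.head(top_k)
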