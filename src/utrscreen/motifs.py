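"""Mechanistic statistics on called variants.

Covers hexamer over-representation between up- and down-regulating sequence
groups, PWM motif-strength changes against shuffled-PWM and nonfunctional-
variant nulls, miRNA target-site overlap with its direction-bias test, RBP
binding-delta comparisons, and distance-to-eCLIP-peak tests.

Motif strength of a sequence under a PWM with uniform base background is
S = prod_i p_i(base_i) / 0.25**n, and the per-variant change is
delta = |S_var - S_ref|.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: rows are positions, columns A/C/G/T(=U)."""

    matrix: tuple  # n x 4, rows sum to 1
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 2:
            raise ValueError("PWM must be n x 4 with n >= 2")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        object.__setattr__(self, "matrix", tuple(map(tuple, m)))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, float)

    def __len__(self) -> int:
        return len(self.matrix)

    def score(self, seq: str) -> float:
        """S = prod p_i / 0.25^n over a sequence of the motif's length."""
        seq = seq.upper()
        if len(seq) != len(self):
            raise ValueError("sequence length must equal motif length")
        m = self.array
        p = 1.0
        for i, b in enumerate(seq):
            p *= m[i, _BASE_INDEX[b]]
        return p / 0.25 ** len(self)

    def shuffle_positions(self, rng: np.random.Generator) -> "PWM":
        """Permute PWM positions (columns of the motif), preserving each
        position's base distribution."""
        m = self.array
        perm = rng.permutation(len(self))
        return PWM(matrix=tuple(map(tuple, m[perm])), name=f"{self.name}:shuffled")


def motif_strength(seq_ref: str, seq_var: str, pwm: PWM, offset: int) -> dict:
    """Strengths of the PWM window at ``offset`` in both alleles and their
    absolute change."""
    n = len(pwm)
    for s in (seq_ref, seq_var):
        if offset < 0 or offset + n > len(s):
            raise ValueError("sequence does not cover the PWM window at offset")
    s_ref = pwm.score(seq_ref[offset:offset + n])
    s_var = pwm.score(seq_var[offset:offset + n])
    return {"S_ref": s_ref, "S_var": s_var, "delta": abs(s_var - s_ref)}


def motif_strength_null(
    functional_pairs,
    pwm: PWM,
    nonfunctional_pairs,
    offsets_functional=None,
    offsets_nonfunctional=None,
    seed: int = 0,
) -> pd.DataFrame:
    """KS comparison of functional motif-strength deltas against two nulls.

    Null 1 recomputes the functional deltas under a position-shuffled PWM;
    null 2 scores a size-matched random sample of nonfunctional variants with
    the original PWM.  ``*_pairs`` are sequences (ref, var); offsets default
    to 0.
    """
    rng = np.random.default_rng(seed)
    functional_pairs = list(functional_pairs)
    nonfunctional_pairs = list(nonfunctional_pairs)
    if len(functional_pairs) < 10 or len(nonfunctional_pairs) < 10:
        raise ValueError("need >= 10 variant pairs per arm")
    if offsets_functional is None:
        offsets_functional = [0] * len(functional_pairs)
    if offsets_nonfunctional is None:
        offsets_nonfunctional = [0] * len(nonfunctional_pairs)

    deltas = np.array([
        motif_strength(r, v, pwm, off)["delta"]
        for (r, v), off in zip(functional_pairs, offsets_functional)
    ])
    shuffled = pwm.shuffle_positions(rng)
    null_shuffled = np.array([
        motif_strength(r, v, shuffled, off)["delta"]
        for (r, v), off in zip(functional_pairs, offsets_functional)
    ])
    idx = rng.choice(len(nonfunctional_pairs),
                     size=min(len(functional_pairs), len(nonfunctional_pairs)),
                     replace=False)
    null_nonfunc = np.array([
        motif_strength(*nonfunctional_pairs[i], pwm, offsets_nonfunctional[i])["delta"]
        for i in idx
    ])
    rows = []
    for label, null in (("shuffled_pwm", null_shuffled),
                        ("nonfunctional", null_nonfunc)):
        d, p = stats.ks_2samp(deltas, null)
        rows.append({"null": label, "ks_D": float(d), "p_value": float(p),
                     "n_functional": len(deltas), "n_null": len(null)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence groups and hexamer enrichment
# ---------------------------------------------------------------------------

def build_sequence_groups(
    calls: pd.DataFrame, design: pd.DataFrame, flank: int = 5,
) -> tuple[list[str], list[str]]:
    """Windows (variant +/- ``flank`` nt) split by effect direction.

    For each functional variant the higher-expressed allele's window joins
    the upregulating group and the lower-expressed allele's window the
    downregulating group, so the two groups always have equal size.  Windows
    truncated at insert ends are kept (shorter than 2*flank+1).
    """
    ins = design.set_index(["variant_id", "allele"])
    up, down = [], []
    for row in calls.itertuples(index=False):
        if not row.functional:
            continue
        windows = {}
        for allele in ("ref", "alt"):
            rec = ins.loc[(row.variant_id, allele)]
            seq, off = rec["insert_sequence"], int(rec["variant_offset"])
            windows[allele] = seq[max(off - flank, 0): off + flank + 1]
        if row.lnFC > 0:
            up.append(windows["alt"]); down.append(windows["ref"])
        else:
            up.append(windows["ref"]); down.append(windows["alt"])
    return up, down


ALL_HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]


def hexamer_enrichment(
    foreground: list[str], background: list[str], fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-hexamer one-sided Fisher exact test of window containment.

    Counts, for every hexamer observed in either group, how many windows
    contain it; tests enrichment in the foreground with a one-sided
    (greater) Fisher exact test on the 2x2 containment table and applies BH
    correction over the tested hexamers.
    """
    if not foreground or not background:
        raise ValueError("both sequence groups must be non-empty")

    def contain_counts(windows):
        counts: dict[str, int] = {}
        for w in windows:
            w = w.upper().replace("U", "T")
            seen = {w[i:i + 6] for i in range(len(w) - 5)}
            for h in seen:
                counts[h] = counts.get(h, 0) + 1
        return counts

    fc = contain_counts(foreground)
    bc = contain_counts(background)
    nf, nb = len(foreground), len(background)
    rows = []
    for h in sorted(set(fc) | set(bc)):
        a = fc.get(h, 0)
        b = bc.get(h, 0)
        _, p = stats.fisher_exact([[a, nf - a], [b, nb - b]], alternative="greater")
        rows.append({"hexamer": h, "fg_count": a, "bg_count": b,
                     "fg_total": nf, "bg_total": nb, "p_value": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method=fdr_method)[1]
        df = df.sort_values(["p_value", "hexamer"]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# miRNA sites and eCLIP peaks
# ---------------------------------------------------------------------------

def overlap_mirna_sites(
    variants: pd.DataFrame, sites: pd.DataFrame, min_percentile: float = 50.0,
) -> pd.DataFrame:
    """Variant x miRNA-site pairs where the (1-based) variant position lies
    inside a predicted site of context++ percentile >= ``min_percentile``.

    Sites use BED convention; sites lacking a percentile are dropped (their
    number is stored in ``df.attrs['n_missing_percentile']``).
    """
    s = sites.copy()
    pct = pd.to_numeric(s.get("percentile"), errors="coerce")
    n_missing = int(pct.isna().sum())
    s = s[pct.notna() & (pct >= min_percentile)]
    rows = []
    for v in variants.itertuples(index=False):
        p0 = v.pos - 1  # to 0-based
        hits = s[(s.chrom == v.chrom) & (s.start <= p0) & (p0 < s.end)]
        for h in hits.itertuples(index=False):
            rows.append({"variant_id": v.variant_id, "site_name": h.name,
                         "chrom": v.chrom, "pos": v.pos,
                         "site_start": h.start, "site_end": h.end})
    out = pd.DataFrame(rows, columns=["variant_id", "site_name", "chrom", "pos",
                                      "site_start", "site_end"])
    out.attrs["n_missing_percentile"] = n_missing
    return out


def direction_bias_test(
    lnfc_overlapping: np.ndarray, lnfc_non_overlapping: np.ndarray,
) -> tuple[float, float]:
    """One-tailed rank-sum: are site-overlapping variants' lnFC shifted up
    (derepression) relative to non-overlapping functional variants?"""
    a = np.asarray(lnfc_overlapping, float)
    b = np.asarray(lnfc_non_overlapping, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both variant sets must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def direction_bias_one_sample(lnfc_overlapping: np.ndarray) -> tuple[float, float]:
    """One-sample alternative: signed-rank test of lnFC against zero."""
    a = np.asarray(lnfc_overlapping, float)
    res = stats.wilcoxon(a, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def rbp_delta_compare(deltas: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Per-RBP KS tests of |binding change| for functional variants against
    nonfunctional and random-SNV controls.

    ``deltas`` columns: rbp, group ('functional' | 'nonfunctional' |
    'random'), delta.  The reported p per RBP is the maximum of the two
    comparisons; BH correction runs across RBPs.  RBPs with any arm smaller
    than ``min_n`` are flagged and skipped.
    """
    rows = []
    for rbp, grp in deltas.groupby("rbp"):
        arms = {
            g: np.abs(sub["delta"].to_numpy(float))
            for g, sub in grp.groupby("group")
        }
        if any(len(arms.get(g, ())) < min_n
               for g in ("functional", "nonfunctional", "random")):
            rows.append({"rbp": rbp, "ks_D_nonfunc": np.nan, "p_nonfunc": np.nan,
                         "ks_D_random": np.nan, "p_random": np.nan,
                         "p_value": np.nan, "skipped": True})
            continue
        d1, p1 = stats.ks_2samp(arms["functional"], arms["nonfunctional"])
        d2, p2 = stats.ks_2samp(arms["functional"], arms["random"])
        rows.append({"rbp": rbp, "ks_D_nonfunc": float(d1), "p_nonfunc": float(p1),
                     "ks_D_random": float(d2), "p_random": float(p2),
                     "p_value": float(max(p1, p2)), "skipped": False})
    df = pd.DataFrame(rows)
    tested = df["p_value"].notna()
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = multipletests(df.loc[tested, "p_value"],
                                              method="fdr_bh")[1]
    return df


def nearest_peak_distance(chrom: str, pos: int, peaks: pd.DataFrame) -> float:
    """Distance from a 1-based variant position to the nearest peak edge.

    Peaks are BED half-open [start, end); the distance is 0 inside a peak,
    otherwise min(|p - start|, |p - (end-1)|) over peaks on the chromosome,
    with ``p = pos - 1``.  NaN when the chromosome has no peaks.
    """
    sub = peaks[peaks.chrom == chrom]
    if sub.empty:
        return np.nan
    p = pos - 1
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    inside = (starts <= p) & (p < ends)
    if inside.any():
        return 0.0
    return float(np.minimum(np.abs(p - starts), np.abs(p - (ends - 1))).min())


def eclip_distance_test(
    variants: pd.DataFrame, peaks: pd.DataFrame,
) -> dict:
    """Are functional variants closer to eCLIP peaks than nonfunctional ones?

    ``variants`` needs chrom, pos (1-based) and a boolean ``functional``
    column.  Returns median distances per group and a one-tailed rank-sum p
    (alternative: functional distances are smaller).
    """
    dists = np.array([
        nearest_peak_distance(v.chrom, v.pos, peaks)
        for v in variants.itertuples(index=False)
    ])
    func = variants["functional"].to_numpy(bool)
    ok = ~np.isnan(dists)
    a, b = dists[ok & func], dists[ok & ~func]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("need both functional and nonfunctional variants")
    res = stats.mannwhitneyu(a, b, alternative="less")
    return {
        "median_functional": float(np.median(a)),
        "median_nonfunctional": float(np.median(b)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_missing": int((~ok).sum()),
    }
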