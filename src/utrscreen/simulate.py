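"""Synthetic data generator for the reporter screen.

Emulates every input the pipeline consumes with known ground truth: a designed
oligo library over random UTR sequences, UMI-family counts for DNA and RNA
libraries, structured paired-end reads with PCR duplicates and substitution
errors, and a patient cohort whose expression and survival are linked to the
variants' true effects.

The count model is gamma-Poisson (negative binomial): UMI-family counts per
oligo are drawn around the configured depth with a single overdispersion
parameter ``dispersion`` (NB variance = m + dispersion * m**2).  Deduplicated
UMI families are molecule counts, so the default dispersion is small
(near-Poisson); it is configurable for noisier regimes.  The RNA mean for the
alternative allele is scaled by ``exp(true_lnFC)``, which is the quantity the
quantification layer estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import design as _design
from .design import (
    LAYOUTS, OligoLayout, DEFAULT_FORBIDDEN, assemble_oligo, oligos_to_frame,
)
from .reads import ReadLayout, DEFAULT_RT_PRIMER, DEFAULT_REC2
from .seq import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """All knobs for the synthetic screen; ``seed`` fully determines output."""

    seed: int = 0
    n_variants: int = 100
    utr_length: int = 400
    flank_design: str = "design2"
    n_replicates: int = 3
    dna_depth: float = 300.0          # mean UMI families per oligo (DNA)
    rna_depth: float = 300.0          # mean UMI families per oligo (RNA)
    pcr_duplication_rate: float = 1.0  # mean reads per UMI family (>= 1)
    error_rate: float = 0.0           # per-base substitution probability
    frac_functional: float = 0.3
    effect_min: float = 0.1           # |lnFC| lower bound for functional variants
    effect_max: float = 1.0
    dispersion: float = 1e-3          # NB alpha for family counts
    baseline_sigma: float = 0.25      # lognormal sd of per-variant RNA baseline
    library_sigma: float = 0.25       # lognormal sd of per-oligo DNA abundance
    # cohort layer
    n_patients: int = 200
    mean_mutations_per_patient: float = 3.0
    expression_shift: float = 1.0     # carrier shift in baseline-sd units
    utmb_hazard_coef: float = 0.3     # log-hazard increment per uTMB unit
    base_hazard: float = 1.0
    censor_max: float = 5.0

    def validate(self) -> None:
        layout = LAYOUTS.get(self.flank_design)
        if layout is None:
            raise ValueError(f"unknown layout {self.flank_design!r}")
        if self.utr_length < layout.insert_len + 2:
            raise ValueError(
                f"utr_length {self.utr_length} shorter than the "
                f"{layout.insert_len}-nt insert requirement"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.pcr_duplication_rate < 1.0:
            raise ValueError("pcr_duplication_rate must be >= 1")
        if not 0.0 <= self.frac_functional <= 1.0:
            raise ValueError("frac_functional must be in [0, 1]")
        for name in ("dna_depth", "rna_depth", "dispersion", "effect_min",
                     "effect_max", "baseline_sigma", "library_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def layout(self) -> OligoLayout:
        return LAYOUTS[self.flank_design]

    def manifest(self) -> dict:
        return asdict(self)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _screened_random_seq(rng, n, forbidden) -> str:
    """Random A/C/G/T sequence free of forbidden substrings on both strands."""
    for _ in range(1000):
        s = _random_seq(rng, n)
        _, fails = _design.screen_sequences([s], forbidden)
        if fails.empty:
            return s
    raise RuntimeError("could not sample a forbidden-substring-free sequence")


def simulate_reference_library(config: SimConfig):
    """Random per-variant UTR sequences plus a variant table.

    Each variant gets its own UTR contig ("chrU<i>") with the variant placed
    at the center so a full flank is always available; the insert-length
    window around the variant is screened against cloning-incompatible
    substrings.  Returns ``(utrs, variants)`` where ``utrs`` maps chrom name
    to sequence and ``variants`` is a VariantRecord table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    utrs: dict[str, str] = {}
    rows = []
    half = config.utr_length // 2
    win_lo = half - layout.insert_len  # generous screened window
    win_hi = half + layout.insert_len
    for i in range(config.n_variants):
        chrom = f"chrU{i}"
        left = _random_seq(rng, max(win_lo, 0))
        mid = _screened_random_seq(rng, min(win_hi, config.utr_length) - max(win_lo, 0),
                                   DEFAULT_FORBIDDEN)
        right = _random_seq(rng, config.utr_length - len(left) - len(mid))
        seq = left + mid + right
        strand = "+" if rng.random() < 0.5 else "-"
        pos = half + 1  # 1-based
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rows.append(
            {
                "variant_id": f"var{i:05d}",
                "chrom": chrom,
                "pos": pos,
                # VCF convention: alleles on the plus strand regardless of
                # the transcribed strand; assembly complements as needed
                "ref": ref,
                "alt": alt,
                "adjAF": float(rng.uniform(0, 0.01)),
                "gene": f"GENE{i:05d}",
                "sources": "gnomad",
                "cosmic_cnt": int(rng.integers(0, 10)),
                "driver_role": str(rng.choice(
                    ["oncogene", "tsg", "ambiguous", "none"], p=[0.2, 0.2, 0.1, 0.5])),
                "strand": strand,
            }
        )
        utrs[chrom] = seq
    variants = pd.DataFrame(rows, columns=_design.VARIANT_COLUMNS)
    return utrs, variants


def simulate_truth(config: SimConfig, variants: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth effects: lnFC = 0 for nulls, |lnFC| in
    [effect_min, effect_max] for functional variants."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(variants)
    functional = rng.random(n) < config.frac_functional
    mag = rng.uniform(config.effect_min, config.effect_max, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    lnfc = np.where(functional, sign * mag, 0.0)
    baseline = np.exp(rng.normal(0.0, config.baseline_sigma, size=n))
    return pd.DataFrame(
        {
            "variant_id": variants["variant_id"].to_numpy(),
            "true_lnFC": lnfc,
            "is_functional": functional,
            "baseline_abundance": baseline,
        }
    )


def build_library(config: SimConfig):
    """Convenience: reference UTRs -> variants -> truth -> assembled oligos."""
    utrs, variants = simulate_reference_library(config)
    truth = simulate_truth(config, variants)
    layout = config.layout
    oligos = []
    for _, var in variants.iterrows():
        oligos.extend(assemble_oligo(var, utrs, layout))
    oligo_df = oligos_to_frame(oligos, layout)
    return utrs, variants, truth, oligo_df


def simulate_counts(
    oligos: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw true UMI-family counts per (oligo, replicate, library type).

    DNA means are ``dna_depth`` scaled by a per-oligo lognormal library
    abundance; RNA means are additionally scaled by the variant's baseline
    abundance and, for the alt allele, ``exp(true_lnFC)``.
    """
    if oligos.empty:
        raise ValueError("empty oligo table")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tr = truth.set_index("variant_id")
    alpha = config.dispersion

    def draw(mean: np.ndarray) -> np.ndarray:
        if alpha <= 1e-12:
            return rng.poisson(mean)
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mean)
        return rng.negative_binomial(n_param, p_param)

    lib_factor = np.exp(rng.normal(0.0, config.library_sigma, size=len(oligos)))
    rows = []
    for (idx, o), lf in zip(oligos.iterrows(), lib_factor):
        t = tr.loc[o.variant_id]
        # RNA output per replicate is proportional to the DNA actually
        # present in that replicate: draw DNA first, then RNA around
        # rate * DNA with rate carrying baseline and allelic effect.
        rate = (config.rna_depth / config.dna_depth) * t.baseline_abundance * (
            np.exp(t.true_lnFC) if o.allele == "alt" else 1.0
        )
        for rep in range(1, config.n_replicates + 1):
            dna = int(draw(np.asarray(config.dna_depth * lf)))
            rna = int(draw(np.asarray(rate * dna))) if dna > 0 else 0
            for lib, fam in (("DNA", dna), ("RNA", rna)):
                rows.append(
                    {
                        "oligo_id": o.oligo_id,
                        "variant_id": o.variant_id,
                        "allele": o.allele,
                        "replicate": rep,
                        "library_type": lib,
                        "dedup": fam,
                    }
                )
    return pd.DataFrame(rows)


def _inject_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class SimulatedReads:
    """Reads plus the family counts they were emitted from."""

    counts: pd.DataFrame
    reads: dict  # (library_type, replicate) -> list of (name, read1, read2)
    read_layout: ReadLayout


def simulate_reads(
    oligos: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    subpool_primer: str | None = None,
    read2_len: int = 150,
) -> SimulatedReads:
    """Emit structured paired reads for every UMI family.

    Read 1 = 15-nt UMI + 14-nt RT primer + 6-nt REC2 site + 15-nt subpool
    primer + first 100 nt of the designed oligo; read 2 = reverse complement
    of the designed oligo (first ``read2_len`` nt).  Each family is emitted
    ``pcr_duplication_rate`` times on average (at least once); substitution
    errors are injected per base at ``error_rate``.
    """
    if oligos.empty:
        raise ValueError("empty oligo table")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    counts = simulate_counts(oligos, truth, config, rng=rng)
    rl = ReadLayout()
    if subpool_primer is None:
        subpool_primer = oligos["full_sequence"].iloc[0][: rl.subpool_len]
    seq_by_oligo = dict(zip(oligos["oligo_id"], oligos["full_sequence"]))

    reads: dict = {
        (lib, rep): []
        for lib in ("DNA", "RNA")
        for rep in range(1, config.n_replicates + 1)
    }
    for row in counts.itertuples(index=False):
        full = seq_by_oligo[row.oligo_id]
        frag = full[: rl.design_frag_len]
        r2_clean = revcomp(full)[:read2_len]
        bucket = reads[(row.library_type, row.replicate)]
        for fam in range(row.dedup):
            umi = _random_seq(rng, rl.umi_len)
            n_copies = 1
            if config.pcr_duplication_rate > 1.0:
                n_copies += int(rng.poisson(config.pcr_duplication_rate - 1.0))
            r1_clean = umi + DEFAULT_RT_PRIMER + DEFAULT_REC2 + subpool_primer + frag
            for copy in range(n_copies):
                name = f"{row.oligo_id}|{row.library_type}|r{row.replicate}|f{fam}|c{copy}"
                r1 = _inject_errors(r1_clean, rng, config.error_rate)
                r2 = _inject_errors(r2_clean, rng, config.error_rate)
                bucket.append((name, r1, r2))
    return SimulatedReads(counts=counts, reads=reads, read_layout=rl)


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortTables:
    mutations: pd.DataFrame   # patient_id, variant_id
    expression: pd.DataFrame  # patients x genes
    survival: pd.DataFrame    # patient_id, time, event, cohort


def simulate_cohort(config: SimConfig, calls: pd.DataFrame) -> CohortTables:
    """Patient cohort with genotype-linked expression and survival.

    Each patient carries a Poisson-distributed random subset of the called
    variants as somatic mutations.  Expression per gene is standard normal,
    shifted by ``expression_shift * sign(lnFC)`` for carriers of a functional
    variant in that gene.  Survival time is exponential with log-hazard
    ``log(base_hazard) + utmb_hazard_coef * uTMB_func``; censoring is
    independent Uniform(0, censor_max).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    calls = calls.reset_index(drop=True)
    variant_ids = calls["variant_id"].to_numpy()
    genes = calls["gene"].to_numpy() if "gene" in calls else variant_ids
    functional = calls["functional"].to_numpy().astype(bool)
    lnfc = calls["lnFC"].to_numpy()

    patients = [f"P{i:04d}" for i in range(config.n_patients)]
    mut_rows = []
    n_func = np.zeros(config.n_patients, dtype=int)
    carrier_shift: dict[tuple[str, str], float] = {}
    for pi, pid in enumerate(patients):
        k = min(int(rng.poisson(config.mean_mutations_per_patient)), len(variant_ids))
        if k == 0:
            continue
        idx = rng.choice(len(variant_ids), size=k, replace=False)
        for j in idx:
            mut_rows.append({"patient_id": pid, "variant_id": variant_ids[j]})
            if functional[j]:
                n_func[pi] += 1
                key = (pid, genes[j])
                carrier_shift[key] = carrier_shift.get(key, 0.0) + (
                    config.expression_shift * np.sign(lnfc[j])
                )
    mutations = pd.DataFrame(mut_rows, columns=["patient_id", "variant_id"])

    uniq_genes = pd.unique(genes)
    expr = rng.normal(0.0, 1.0, size=(config.n_patients, len(uniq_genes)))
    gene_idx = {g: j for j, g in enumerate(uniq_genes)}
    for (pid, g), shift in carrier_shift.items():
        expr[patients.index(pid), gene_idx[g]] += shift
    expression = pd.DataFrame(expr, index=patients, columns=uniq_genes)
    expression.index.name = "patient_id"

    hazard = config.base_hazard * np.exp(config.utmb_hazard_coef * n_func)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, config.censor_max, size=config.n_patients)
    event = t_event <= t_censor
    survival = pd.DataFrame(
        {
            "patient_id": patients,
            "time": np.minimum(t_event, t_censor),
            "event": event,
            "cohort": "SIM",
        }
    )
    return CohortTables(mutations=mutations, expression=expression, survival=survival)
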