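"""Synthetic factorial splicing/expression datasets with known ground truth.

Generates event-level inclusion/skipping junction counts, gene-level counts
and splice-acceptor context sequences for a 2x2 genotype x treatment design
(five replicates per cell by default).  Per-event condition PSI is
logit-additive in mutation and drug effects with an optional interaction
term; counts are beta-binomial around the condition PSI with negative-
binomial per-sample totals.  Drug effects are biased toward exon skipping
(SE) and intron retention (RI); mutation-sensitive events carry an elevated
T frequency at the -3 intronic acceptor position.

A single numpy Generator seeded from ``config.seed`` drives every draw, in a
fixed order (event attributes, then per-event/sample counts, then gene
counts, then sequences), so identical configs yield identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from .events import CONDITIONS, JunctionCountTable, SpliceEvent

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "logit_psi_model",
    "sample_event_counts",
    "simulate_acceptor_sequence",
    "simulate_factorial_experiment",
]

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the generative model; see module docstring."""

    n_events: int = 4000
    n_genes: int = 1000
    replicates_per_condition: int = 5
    frac_se: float = 0.8  # remainder are RI events
    baseline_psi_alpha: float = 2.0
    baseline_psi_beta: float = 2.0
    frac_mut_sensitive: float = 0.15
    frac_drug_sensitive: float = 0.15
    frac_interacting: float = 0.0
    beta_mut: float = 1.0
    beta_drug: float = 1.0
    beta_int: float = 1.5
    skip_bias_drug: float = 0.6
    coverage_mean: float = 60.0
    coverage_dispersion: float = 0.15
    bb_overdispersion: float = 0.02
    expr_log2fc_mut: float = 1.5
    expr_log2fc_drug: float = 1.5
    frac_de_genes: float = 0.1
    nb_gene_dispersion: float = 0.05
    gene_mean_log: float = 4.5
    gene_mean_sd: float = 1.0
    motif_t_minus3_sensitive: float = 0.8
    motif_t_minus3_background: float = 0.25
    context_window: tuple = (20, 3)  # (intronic, exonic) lengths
    seed: int = 0

    def __post_init__(self):
        props = {
            "frac_se": self.frac_se,
            "frac_mut_sensitive": self.frac_mut_sensitive,
            "frac_drug_sensitive": self.frac_drug_sensitive,
            "frac_interacting": self.frac_interacting,
            "skip_bias_drug": self.skip_bias_drug,
            "frac_de_genes": self.frac_de_genes,
            "motif_t_minus3_sensitive": self.motif_t_minus3_sensitive,
            "motif_t_minus3_background": self.motif_t_minus3_background,
        }
        for name, v in props.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.frac_interacting > min(
            self.frac_mut_sensitive, self.frac_drug_sensitive
        ) + 1e-12:
            raise ValueError(
                "frac_interacting must not exceed min(frac_mut_sensitive,"
                " frac_drug_sensitive)"
            )
        if self.n_events < 1 or self.n_genes < 1:
            raise ValueError("n_events and n_genes must be positive")
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if not (0.0 <= self.bb_overdispersion < 1.0):
            raise ValueError("bb_overdispersion must lie in [0, 1)")
        if self.baseline_psi_alpha <= 0 or self.baseline_psi_beta <= 0:
            raise ValueError("beta prior parameters must be positive")
        if self.nb_gene_dispersion <= 0:
            raise ValueError("nb_gene_dispersion must be positive")
        iw, ew = self.context_window
        if iw < 3 or ew < 0:
            raise ValueError("context_window intronic length must be >= 3")
        for name in ("beta_mut", "beta_drug", "beta_int"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        self.context_window = (int(iw), int(ew))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["context_window"] = list(self.context_window)
        return d


@dataclass
class SyntheticDataset:
    """Counts, truth and sequences produced by one simulation run."""

    junction_counts: JunctionCountTable
    gene_counts: pd.DataFrame
    event_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    acceptor_sequences: dict
    config: SimulationConfig


def logit_psi_model(
    beta0: float,
    beta_mut: float,
    beta_drug: float,
    beta_int: float,
    is_mut: bool,
    is_drug: bool,
) -> float:
    """Condition PSI under the logit-additive effect model."""
    for v in (beta0, beta_mut, beta_drug, beta_int):
        if not math.isfinite(v):
            raise ValueError("coefficients must be finite")
    eta = beta0 + beta_mut * is_mut + beta_drug * is_drug + beta_int * (is_mut and is_drug)
    return float(special.expit(eta))


def sample_event_counts(psi: float, total: int, rho: float, rng) -> tuple:
    """Draw (inclusion, skipping) summing to ``total``.

    Inclusion is beta-binomial(total, psi, rho) where ``rho`` is the
    intra-class correlation; rho=0 degenerates to binomial.
    """
    if not (0.0 <= psi <= 1.0):
        raise ValueError("psi must lie in [0, 1]")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if total < 0:
        raise ValueError("total must be non-negative")
    if total == 0:
        return 0, 0
    if psi in (0.0, 1.0) or rho == 0.0:
        inc = int(rng.binomial(total, psi))
        return inc, total - inc
    s = (1.0 - rho) / rho
    p = rng.beta(psi * s, (1.0 - psi) * s)
    inc = int(rng.binomial(total, p))
    return inc, total - inc


def simulate_acceptor_sequence(
    is_mut_sensitive: bool, config: SimulationConfig, rng
) -> str:
    """Fixed-length 3' splice-acceptor context with canonical AG at the
    intronic -2/-1 positions and a sensitivity-dependent T frequency at -3."""
    iw, ew = config.context_window
    n = iw + ew
    seq = list(rng.choice(BASES, size=n))
    # intronic positions are indices 0..iw-1 (position -iw..-1)
    p_t = (
        config.motif_t_minus3_sensitive
        if is_mut_sensitive
        else config.motif_t_minus3_background
    )
    if rng.random() < p_t:
        seq[iw - 3] = "T"
    else:
        seq[iw - 3] = str(rng.choice(np.array(list("ACG"))))
    seq[iw - 2] = "A"
    seq[iw - 1] = "G"
    return "".join(seq)


def _inclusion_fraction(psi: float, inc_norm: int, skip_norm: int) -> float:
    """Expected raw inclusion-read fraction for a target normalized PSI."""
    num = inc_norm * psi
    return num / (num + skip_norm * (1.0 - psi))


def simulate_factorial_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    n_se = int(round(config.frac_se * n))

    n_mut = int(round(config.frac_mut_sensitive * n))
    n_drug = int(round(config.frac_drug_sensitive * n))
    n_int = int(round(config.frac_interacting * n))
    if n_int > min(n_mut, n_drug):
        raise ValueError("infeasible sensitivity fractions for n_events")

    # index layout over a random permutation: interacting events first (they
    # are both mut- and drug-sensitive), then drug-sensitive events drawn
    # preferentially from non-mut indices, overlapping into mut-sensitive
    # (with beta_int = 0) only when unavoidable
    perm = rng.permutation(n)
    mut_sensitive = np.zeros(n, dtype=bool)
    drug_sensitive = np.zeros(n, dtype=bool)
    interacting = np.zeros(n, dtype=bool)
    mut_sensitive[perm[:n_mut]] = True
    interacting[perm[:n_int]] = True
    drug_sensitive[perm[:n_int]] = True
    n_remaining = n_drug - n_int
    tail = min(n_remaining, n - n_mut)
    drug_sensitive[perm[n_mut : n_mut + tail]] = True
    if n_remaining > tail:  # overlap with non-interacting mut events
        drug_sensitive[perm[n_int : n_int + (n_remaining - tail)]] = True

    event_types = np.array(["SE"] * n_se + ["RI"] * (n - n_se))

    base_psi = rng.beta(config.baseline_psi_alpha, config.baseline_psi_beta, size=n)
    base_psi = np.clip(base_psi, 0.02, 0.98)
    beta0 = special.logit(base_psi)

    # Effect signs.  Drug: negative logit effect = less inclusion = more
    # skipping for SE; for RI the drug bias is toward retention (positive).
    b_mut = np.zeros(n)
    b_drug = np.zeros(n)
    b_int = np.zeros(n)
    mut_sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    drug_toward = rng.random(n) < config.skip_bias_drug
    drug_sign = np.where(
        event_types == "SE",
        np.where(drug_toward, -1.0, 1.0),
        np.where(drug_toward, 1.0, -1.0),
    )
    int_sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    b_mut[mut_sensitive] = mut_sign[mut_sensitive] * config.beta_mut
    b_drug[drug_sensitive] = drug_sign[drug_sensitive] * config.beta_drug
    b_int[interacting] = int_sign[interacting] * config.beta_int

    reps = config.replicates_per_condition
    samples = [f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(reps)]
    sample_conditions = {
        s: cond for cond in CONDITIONS for s in [f"{cond}_{r + 1}" for r in range(reps)]
    }
    cond_flags = {
        "WT_Veh": (False, False),
        "WT_Drug": (False, True),
        "MT_Veh": (True, False),
        "MT_Drug": (True, True),
    }

    events = []
    gene_of_event = rng.integers(0, config.n_genes, size=n)
    for i in range(n):
        etype = event_types[i]
        start = 1000 + 5000 * i
        if etype == "SE":
            coords = (start, start + 300, start + 400, start + 900)
        else:
            coords = (start, start + 500)
        events.append(
            SpliceEvent(
                event_id=f"ev{i:05d}",
                gene_id=f"g{gene_of_event[i]:04d}",
                event_type=etype,
                chrom="chr1",
                coordinates=coords,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )

    nb_r = 1.0 / config.coverage_dispersion
    nb_p = nb_r / (nb_r + config.coverage_mean)
    totals = rng.negative_binomial(nb_r, nb_p, size=(n, len(samples)))

    inc = np.zeros((n, len(samples)), dtype=int)
    skp = np.zeros((n, len(samples)), dtype=int)
    psi_cond = np.zeros((n, 4))
    for i, ev in enumerate(events):
        for c, cond in enumerate(CONDITIONS):
            is_mut, is_drug = cond_flags[cond]
            psi_cond[i, c] = logit_psi_model(
                beta0[i], b_mut[i], b_drug[i], b_int[i], is_mut, is_drug
            )
        for j, s in enumerate(samples):
            c = CONDITIONS.index(sample_conditions[s])
            f = _inclusion_fraction(
                psi_cond[i, c], ev.inc_junction_count, ev.skip_junction_count
            )
            inc[i, j], skp[i, j] = sample_event_counts(
                f, int(totals[i, j]), config.bb_overdispersion, rng
            )

    event_ids = [e.event_id for e in events]
    table = JunctionCountTable(
        events=events,
        inclusion_counts=pd.DataFrame(inc, index=event_ids, columns=samples),
        skipping_counts=pd.DataFrame(skp, index=event_ids, columns=samples),
        sample_conditions=sample_conditions,
    )

    event_truth = pd.DataFrame(
        {
            "event_id": event_ids,
            "gene_id": [e.gene_id for e in events],
            "event_type": event_types,
            "baseline_psi": base_psi,
            "beta_mut": b_mut,
            "beta_drug": b_drug,
            "beta_int": b_int,
            "mut_sensitive": mut_sensitive,
            "drug_sensitive": drug_sensitive,
            "interacting": interacting,
            "drug_direction": np.where(
                drug_sensitive,
                np.where(
                    event_types == "SE",
                    np.where(drug_sign < 0, "skipping", "inclusion"),
                    np.where(drug_sign > 0, "retention", "removal"),
                ),
                "none",
            ),
            "psi_WT_Veh": psi_cond[:, 0],
            "psi_WT_Drug": psi_cond[:, 1],
            "psi_MT_Veh": psi_cond[:, 2],
            "psi_MT_Drug": psi_cond[:, 3],
        }
    ).set_index("event_id", drop=False)

    # ---- gene-level counts -------------------------------------------------
    g = config.n_genes
    n_de = int(round(config.frac_de_genes * g))
    gperm = rng.permutation(g)
    mut_de = np.zeros(g, dtype=bool)
    drug_de = np.zeros(g, dtype=bool)
    mut_de[gperm[: n_de // 2]] = True
    drug_de[gperm[n_de // 2 : n_de]] = True
    lfc_mut = np.where(
        mut_de, np.where(rng.random(g) < 0.5, -1, 1) * config.expr_log2fc_mut, 0.0
    )
    lfc_drug = np.where(
        drug_de, np.where(rng.random(g) < 0.5, -1, 1) * config.expr_log2fc_drug, 0.0
    )
    base_mean = np.exp(rng.normal(config.gene_mean_log, config.gene_mean_sd, size=g))
    gene_ids = [f"g{i:04d}" for i in range(g)]
    gcounts = np.zeros((g, len(samples)), dtype=int)
    r_g = 1.0 / config.nb_gene_dispersion
    for j, s in enumerate(samples):
        is_mut, is_drug = cond_flags[sample_conditions[s]]
        mu = base_mean * 2.0 ** (lfc_mut * is_mut + lfc_drug * is_drug)
        p = r_g / (r_g + mu)
        gcounts[:, j] = rng.negative_binomial(r_g, p)
    gene_counts = pd.DataFrame(gcounts, index=gene_ids, columns=samples)
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": base_mean,
            "log2fc_mut": lfc_mut,
            "log2fc_drug": lfc_drug,
            "de_mut": mut_de,
            "de_drug": drug_de,
        }
    ).set_index("gene_id", drop=False)

    sequences = {
        e.event_id: simulate_acceptor_sequence(bool(mut_sensitive[i]), config, rng)
        for i, e in enumerate(events)
    }

    return SyntheticDataset(
        junction_counts=table,
        gene_counts=gene_counts,
        event_truth=event_truth,
        gene_truth=gene_truth,
        acceptor_sequences=sequences,
        config=config,
    )
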