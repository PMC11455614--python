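"""Seeded synthetic-data generators with ground truth for every pipeline input.

Each generator is a pure function of its spec (seed included) and returns
the generated data together with a truth table, so recovery tests can
compare estimates against the generating parameters. Default scales are
sized for sub-minute generation on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bandit_task import STANDARD_TASK, SessionLog, TaskConfig
from .ephys_fit import PowerSweep, hill_sigmoid
from .pseudocell_de import NucleusCounts
from .qlearning import QParams, simulate_agent
from .syllable_metrics import SyllableStream

__all__ = [
    "CohortSpec",
    "CountsSpec",
    "SweepSpec",
    "SyllableSpec",
    "gen_cohort",
    "gen_counts",
    "gen_psc_sweeps",
    "gen_syllable_streams",
]


# ---------------------------------------------------------------------------
# Behavioral cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Simulated cohort: per-mouse parameters from uniform priors, with a
    multiplicative shift of the inverse temperature in the treatment epoch."""

    n_mice: int = 12
    sessions_per_epoch: int = 10
    trials_per_session: int = 300
    alpha_range: tuple[float, float] = (0.4, 0.8)
    zeta_range: tuple[float, float] = (0.1, 0.5)
    beta_range: tuple[float, float] = (1.5, 3.5)
    bias_range: tuple[float, float] = (-0.3, 0.3)
    beta_treatment_factor: float = 0.7
    task: TaskConfig = STANDARD_TASK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_treatment_factor <= 0:
            raise ValueError("beta_treatment_factor must be positive")


def gen_cohort(spec: CohortSpec) -> tuple[list[SessionLog], pd.DataFrame]:
    """Simulate a cohort; returns (session logs, per-mouse truth table)."""
    root = np.random.default_rng(spec.seed)
    mouse_seeds = root.integers(0, 2**31 - 1, size=(spec.n_mice, 2))
    logs: list[SessionLog] = []
    truth_rows = []
    for m in range(spec.n_mice):
        mouse_id = f"m{m:03d}"
        params = QParams(
            alpha=float(root.uniform(*spec.alpha_range)),
            zeta=float(root.uniform(*spec.zeta_range)),
            beta=float(root.uniform(*spec.beta_range)),
            bias=float(root.uniform(*spec.bias_range)),
        )
        beta_treat = params.beta * spec.beta_treatment_factor
        for epoch, beta, seed in (
            ("habituation", params.beta, mouse_seeds[m, 0]),
            ("treatment", beta_treat, mouse_seeds[m, 1]),
        ):
            p = QParams(alpha=params.alpha, zeta=params.zeta, beta=beta, bias=params.bias)
            logs.extend(
                simulate_agent(
                    p,
                    spec.task,
                    spec.sessions_per_epoch,
                    int(seed),
                    mouse_id=mouse_id,
                    epoch=epoch,
                )
            )
        truth_rows.append(
            {
                "mouse_id": mouse_id,
                "alpha": params.alpha,
                "zeta": params.zeta,
                "beta_habituation": params.beta,
                "beta_treatment": beta_treat,
                "bias": params.bias,
            }
        )
    return logs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Negative-binomial nucleus counts


@dataclass(frozen=True)
class CountsSpec:
    n_genes: int = 2000
    n_samples_per_condition: int = 4
    nuclei_per_sample: int = 240
    mean_log_expr: float = -1.0  # lognormal(mean, sd) of per-gene base rates
    sd_log_expr: float = 1.5
    library_size_sd: float = 0.2  # lognormal sd of per-nucleus depth factors
    dispersion: float = 0.5  # NB shape (smaller = more overdispersed)
    sample_effect_sd: float = 0.05  # per-sample, per-gene log2 random intercepts
    spike_fraction: float = 0.04
    spike_log2fc_range: tuple[float, float] = (1.0, 2.0)
    pct_mt_effect: float = 0.0  # log2 expression shift per pct_mt unit
    cell_type: str = "neuron"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.spike_fraction <= 1.0):
            raise ValueError("spike_fraction must be in [0,1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def gen_counts(spec: CountsSpec) -> tuple[NucleusCounts, pd.DataFrame]:
    """Negative-binomial counts with sample-level random intercepts and
    spiked condition effects; returns (nuclei, truth table of spiked genes).

    Spiked genes have their mean multiplied by 2**log2fc in the T3
    condition; half the spikes are down-regulated (negative log2fc).
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    base = rng.lognormal(spec.mean_log_expr, spec.sd_log_expr, size=G)

    n_spike = int(round(spec.spike_fraction * G))
    spike_idx = rng.choice(G, size=n_spike, replace=False)
    lfc = np.zeros(G)
    if n_spike:
        mags = rng.uniform(*spec.spike_log2fc_range, size=n_spike)
        signs = np.where(rng.random(n_spike) < 0.5, -1.0, 1.0)
        lfc[spike_idx] = mags * signs

    genes = np.array([f"g{i:05d}" for i in range(G)])
    blocks, meta_rows = [], []
    for cond in ("control", "T3"):
        for s in range(spec.n_samples_per_condition):
            sid = f"{cond}_s{s}"
            n = spec.nuclei_per_sample
            sample_shift = rng.normal(0.0, spec.sample_effect_sd, size=G)
            mu_g = base * 2.0 ** (sample_shift + (lfc if cond == "T3" else 0.0))
            depth = rng.lognormal(0.0, spec.library_size_sd, size=n)
            pct_mt = rng.uniform(0.5, 5.0, size=n)
            mu = mu_g[:, None] * depth[None, :]
            if spec.pct_mt_effect:
                mu = mu * 2.0 ** (spec.pct_mt_effect * pct_mt[None, :])
            r = spec.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            blocks.append(sp.csc_matrix(counts))
            n_genes_det = (counts > 0).sum(axis=0)
            for j in range(n):
                meta_rows.append(
                    {
                        "cell_type": spec.cell_type,
                        "sample_id": sid,
                        "condition": cond,
                        "cre_status": "n/a",
                        "pct_mt": pct_mt[j],
                        "n_genes": int(n_genes_det[j]),
                    }
                )
    nuclei = NucleusCounts(
        counts=sp.hstack(blocks, format="csc"),
        genes=genes,
        meta=pd.DataFrame(meta_rows),
    )
    truth = pd.DataFrame(
        {"gene": genes, "log2fc": lfc, "spiked": lfc != 0, "base_mean": base}
    )
    return nuclei, truth


# ---------------------------------------------------------------------------
# Hill-sigmoid power sweeps


@dataclass(frozen=True)
class SweepSpec:
    n_cells_per_condition: int = 20
    powers_mw: tuple[float, ...] = (0.03, 0.06, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0)
    amp_mean: float = 2.0
    half_power_mean: float = 0.5
    hill_slope_mean: float = 1.8
    cell_jitter_sd: float = 0.15  # lognormal sd of per-cell parameter jitter
    noise_sd: float = 0.05  # multiplicative Gaussian noise on charges
    amp_t3_factor: float = 1.5
    half_power_t3_factor: float = 0.7
    seed: int = 0


def gen_psc_sweeps(spec: SweepSpec) -> tuple[list[PowerSweep], pd.DataFrame]:
    """Per-cell Hill sweeps with parameter jitter and multiplicative noise."""
    rng = np.random.default_rng(spec.seed)
    powers = np.asarray(spec.powers_mw, dtype=float)
    sweeps, rows = [], []
    for cond in ("control", "T3"):
        fa = spec.amp_t3_factor if cond == "T3" else 1.0
        fh = spec.half_power_t3_factor if cond == "T3" else 1.0
        for c in range(spec.n_cells_per_condition):
            cell_id = f"{cond}_c{c:02d}"
            amp = spec.amp_mean * fa * rng.lognormal(0.0, spec.cell_jitter_sd)
            half = spec.half_power_mean * fh * rng.lognormal(0.0, spec.cell_jitter_sd)
            slope = spec.hill_slope_mean * rng.lognormal(0.0, spec.cell_jitter_sd)
            y = hill_sigmoid(powers, amp, half, slope)
            if spec.noise_sd > 0:
                y = y * (1.0 + rng.normal(0.0, spec.noise_sd, size=len(powers)))
            sweeps.append(
                PowerSweep(
                    cell_id=cell_id,
                    condition=cond,
                    cm_pf=float(rng.uniform(80.0, 150.0)),
                    powers_mw=powers,
                    charges=y,
                )
            )
            rows.append(
                {
                    "cell_id": cell_id,
                    "condition": cond,
                    "amp": amp,
                    "half_power": half,
                    "hill_slope": slope,
                }
            )
    return sweeps, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Markov syllable streams


@dataclass(frozen=True)
class SyllableSpec:
    n_syllables: int = 12
    n_sessions: int = 6
    n_instances: int = 2000
    mean_run_length: float = 8.0  # geometric run lengths (frames)
    stochasticity: float = 1.0  # 1 = uniform off-diagonal, 0 = deterministic cycle
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.stochasticity <= 1.0):
            raise ValueError("stochasticity must be in [0,1]")
        if self.n_syllables < 2:
            raise ValueError("need >= 2 syllables")


def _transition_matrix(spec: SyllableSpec) -> np.ndarray:
    """No-self-transition matrix blending a deterministic cycle with the
    uniform off-diagonal distribution."""
    K = spec.n_syllables
    cycle = np.zeros((K, K))
    cycle[np.arange(K), (np.arange(K) + 1) % K] = 1.0
    uniform = (np.ones((K, K)) - np.eye(K)) / (K - 1)
    T = (1.0 - spec.stochasticity) * cycle + spec.stochasticity * uniform
    return T / T.sum(axis=1, keepdims=True)


def gen_syllable_streams(spec: SyllableSpec) -> tuple[list[SyllableStream], np.ndarray]:
    """First-order Markov instance chains expanded to frame level with
    geometric run lengths; returns (streams, true transition matrix)."""
    rng = np.random.default_rng(spec.seed)
    T = _transition_matrix(spec)
    K = spec.n_syllables
    p_next = 1.0 / spec.mean_run_length
    streams = []
    for s in range(spec.n_sessions):
        state = int(rng.integers(K))
        frames = []
        for _ in range(spec.n_instances):
            run = int(rng.geometric(p_next))
            frames.extend([state] * run)
            state = int(rng.choice(K, p=T[state]))
        streams.append(SyllableStream(session_id=f"sess{s:02d}", labels=np.array(frames)))
    return streams, T
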