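"""Synthetic RNA-seq count simulator with ground-truth DE labels.

The generative model mirrors the study design used throughout the package's
benchmarks. For m genes and n samples:

* gene lengths      l_i  ~ exp(Unif(5, 10))
* gene log offsets  a_i  ~ N(0, 1)
* covariates        x_j  ~ N(0, 1)   (per covariate, i.i.d.)
* library sizes     N_j  ~ Unif(2e6, 3e6)
* sample offsets    d_j  ~ N(0, 1)
* DE coefficients: a round(de_fraction*m) subset of genes is differentially
  expressed; of those, round(up_fraction * #DE) are up-regulated with
  beta_i ~ N(2, 1), the rest down-regulated with beta_i ~ N(-2, 1);
  all other genes have beta_i = 0.

Mean counts are mu_ij = N_j * (l_i / sum_i l_i) * exp(a_i + beta_i'x_j + d_j)
and observed counts are drawn either as ceil(exp(N(log mu_ij, sigma_i^2)))
(log-normal noise; counts are then >= 1) or as NB(mu_ij, phi) with variance
mu + phi*mu^2 (gamma-Poisson mixture with shape 1/phi; phi = 0 degenerates
to Poisson).

Randomness is split into named substreams (gene-level, sample-level, noise)
spawned from one seed, so e.g. changing n does not perturb the gene-level
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centering import LogExpressionMatrix, _default_ids
from .exceptions import ValidationError

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "log_transform",
]

NOISE_MODELS = ("lognormal", "negbinom")


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one simulated dataset.

    Defaults are the benchmark conditions: log-normal noise with
    sigma2 = 0.01, NB dispersion phi = 0.25 when `noise="negbinom"`,
    one covariate.
    """

    m: int = 20000
    n: int = 20
    p: int = 1
    de_fraction: float = 0.10
    up_fraction: float = 0.50
    noise: str = "lognormal"
    sigma2: float = 0.01
    dispersion: float = 0.25
    seed: int = 0
    #: standard deviation of the sample offsets d_j; 0 disables them
    #: (diagnostic runs checking that column sums track library size).
    sample_offset_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 2 or self.p < 1:
            raise ValidationError("require m >= 1, n >= 2, p >= 1")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValidationError("de_fraction must lie in [0, 1]")
        if not (0.0 <= self.up_fraction <= 1.0):
            raise ValidationError("up_fraction must lie in [0, 1]")
        if self.noise not in NOISE_MODELS:
            raise ValidationError(f"noise must be one of {NOISE_MODELS}")
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")
        if self.sample_offset_sd < 0:
            raise ValidationError("sample_offset_sd must be non-negative")
        if self.n_de > self.m:
            raise ValidationError("rounded DE count exceeds the gene count")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.m))

    @property
    def n_up(self) -> int:
        return int(round(self.up_fraction * self.n_de))


@dataclass
class SimulatedDataset:
    """Counts plus every latent quantity used to generate them."""

    counts: np.ndarray          # (m, n) non-negative integers
    truth_beta: np.ndarray      # (m, p)
    de_labels: np.ndarray       # (m,) bool, beta_i != 0
    covariates: np.ndarray      # (n, p)
    library_sizes: np.ndarray   # (n,)
    gene_lengths: np.ndarray    # (m,)
    sample_offsets: np.ndarray  # (n,)
    gene_offsets: np.ndarray    # (m,)
    mean_counts: np.ndarray     # (m, n)
    config: SimulationConfig
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = _default_ids("gene_", self.counts.shape[0])
        if not self.sample_ids:
            self.sample_ids = _default_ids("sample_", self.counts.shape[1])


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic dataset under `config`. Bit-reproducible per seed."""
    m, n, p = config.m, config.n, config.p
    gene_ss, sample_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(3)
    gene_rng = np.random.default_rng(gene_ss)
    sample_rng = np.random.default_rng(sample_ss)
    noise_rng = np.random.default_rng(noise_ss)

    lengths = np.exp(gene_rng.uniform(5.0, 10.0, size=m))
    alpha = gene_rng.standard_normal(m)
    perm = gene_rng.permutation(m)

    n_de, n_up = config.n_de, config.n_up
    beta = np.zeros((m, p))
    up_idx = perm[:n_up]
    down_idx = perm[n_up:n_de]
    beta[up_idx] = gene_rng.normal(2.0, 1.0, size=(n_up, p))
    beta[down_idx] = gene_rng.normal(-2.0, 1.0, size=(n_de - n_up, p))
    de_labels = np.zeros(m, dtype=bool)
    de_labels[perm[:n_de]] = True

    x = sample_rng.standard_normal((n, p))
    libsize = sample_rng.uniform(2e6, 3e6, size=n)
    d = sample_rng.normal(0.0, config.sample_offset_sd, size=n)

    log_mu = (
        np.log(libsize)[None, :]
        + np.log(lengths / lengths.sum())[:, None]
        + alpha[:, None]
        + beta @ x.T
        + d[None, :]
    )
    mu = np.exp(log_mu)

    if config.noise == "lognormal":
        draws = noise_rng.normal(log_mu, np.sqrt(config.sigma2))
        counts = np.ceil(np.exp(draws)).astype(np.int64)
    else:
        phi = config.dispersion
        if phi == 0.0:
            counts = noise_rng.poisson(mu).astype(np.int64)
        else:
            lam = noise_rng.gamma(shape=1.0 / phi, scale=phi * mu)
            counts = noise_rng.poisson(lam).astype(np.int64)

    return SimulatedDataset(
        counts=counts,
        truth_beta=beta,
        de_labels=de_labels,
        covariates=x,
        library_sizes=libsize,
        gene_lengths=lengths,
        sample_offsets=d,
        gene_offsets=alpha,
        mean_counts=mu,
        config=config,
    )


def log_transform(counts, pseudocount: float = 1.0,
                  gene_ids=None, sample_ids=None) -> LogExpressionMatrix:
    """Natural log of counts + pseudocount.

    A pseudocount of 0 is allowed only when every count is positive.
    Accepts a SimulatedDataset, in which case its ids are carried over.
    """
    if isinstance(counts, SimulatedDataset):
        gene_ids = gene_ids or counts.gene_ids
        sample_ids = sample_ids or counts.sample_ids
        counts = counts.counts
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(c == 0):
        raise ValidationError("pseudocount 0 requires strictly positive counts")
    return LogExpressionMatrix(
        values=np.log(c + pseudocount),
        gene_ids=list(gene_ids) if gene_ids else [],
        sample_ids=list(sample_ids) if sample_ids else [],
    )
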