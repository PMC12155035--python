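"""Simulated phenotypes over the deme grid.

Three architectures, chosen to separate environmental from genetic
confounding:

* ``smooth`` -- a purely environmental north-south cline: each sample's
  value is Normal(mean_row, sigma^2) with the row mean decreasing linearly
  from 2*sigma on the top row to 0 on the bottom row.  Heritability is zero
  by construction.
* ``sharp`` -- a purely environmental point effect: one target deme has
  mean mu (and optionally doubled standard deviation); every other deme is
  Normal(0, sigma^2).  This violates any linear-in-coordinates model.
* ``polygenic`` -- heritable with no environmental term: one causal SNP is
  drawn uniformly from every 1 kb window that contains a segregating site,
  effect sizes are Normal(0, [2 p (1-p)]^alpha) so that (at the default
  alpha = -1) each causal variant contributes equally in expectation
  regardless of frequency, and the genetic score is rescaled in-sample so
  the realized narrow-sense heritability equals h2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .io_core import GenotypeMatrix

__all__ = ["PhenotypeSpec", "PhenotypeResult", "simulate_smooth",
           "simulate_sharp", "simulate_polygenic", "simulate_noise"]


@dataclass(frozen=True)
class PhenotypeSpec:
    """Parameters shared by the three phenotype generators.

    ``sigma`` is the environmental standard deviation (trait units); ``mu``
    the sharp-deme mean (defaults to 2*sigma); ``sharp_sd_multiplier``
    scales the target deme's standard deviation (1 or 2 -- both variants
    appear in the literature); ``h2`` the exact in-sample heritability of
    the polygenic trait; ``alpha`` the frequency-scaling exponent of effect
    sizes; ``window_bp`` the causal-SNP window width.
    """

    kind: str = "smooth"
    sigma: float = 1.0
    mu: Optional[float] = None
    target_deme: Tuple[int, int] = (0, 0)
    sharp_sd_multiplier: float = 1.0
    h2: float = 0.8
    alpha: float = -1.0
    window_bp: int = 1000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if self.sharp_sd_multiplier <= 0:
            raise ValueError("sharp_sd_multiplier must be positive")


@dataclass
class PhenotypeResult:
    """Per-sample values plus (for the polygenic kind) the causal truth."""

    values: np.ndarray
    causal_set: Optional[pd.DataFrame] = None  # columns: variant_index, beta
    realized_h2: Optional[float] = None


def _row_means(rows: np.ndarray, sigma: float) -> np.ndarray:
    R = int(rows.max()) + 1
    if R < 2:
        raise ValueError("smooth phenotype needs a grid with at least 2 rows")
    return 2.0 * sigma * (R - 1 - rows) / (R - 1)


def simulate_smooth(labels: np.ndarray, spec: PhenotypeSpec) -> PhenotypeResult:
    """North-south cline: row mean runs linearly from 2*sigma down to 0."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    means = _row_means(labels[:, 0].astype(float), spec.sigma)
    return PhenotypeResult(values=rng.normal(means, spec.sigma))


def simulate_sharp(labels: np.ndarray, spec: PhenotypeSpec) -> PhenotypeResult:
    """Point effect: Normal(mu, (m*sigma)^2) at the target deme, else Normal(0, sigma^2)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    tr, tc = spec.target_deme
    if not ((labels[:, 0] == tr) & (labels[:, 1] == tc)).any():
        raise ValueError(f"target deme {spec.target_deme} is not on the grid")
    mu = 2.0 * spec.sigma if spec.mu is None else spec.mu
    on_target = (labels[:, 0] == tr) & (labels[:, 1] == tc)
    sd = np.where(on_target, spec.sharp_sd_multiplier * spec.sigma, spec.sigma)
    means = np.where(on_target, mu, 0.0)
    return PhenotypeResult(values=rng.normal(means, sd))


def simulate_noise(n: int, spec: PhenotypeSpec) -> PhenotypeResult:
    """Pure Normal(0, sigma^2) noise -- the null phenotype for calibration."""
    rng = np.random.default_rng(spec.seed)
    return PhenotypeResult(values=rng.normal(0.0, spec.sigma, size=n))


def simulate_polygenic(g: GenotypeMatrix, spec: PhenotypeSpec) -> PhenotypeResult:
    """Heritable trait with frequency-scaled effects and exact in-sample h2.

    The raw genetic score G = X beta is centred and rescaled to variance
    h2; the noise term is drawn, orthogonalized against G in-sample, and
    rescaled to variance 1 - h2, so Var(G)/Var(y) is h2 to machine
    precision.  Monomorphic variants are never eligible as causal.
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    rng = np.random.default_rng(spec.seed)
    p = g.allele_freqs
    eligible = (p > 0) & (p < 1)
    if not eligible.any():
        raise ValueError("no segregating sites available for causal selection")

    # one causal pick per half-open [w*window, (w+1)*window) bp window per
    # chromosome; windows without a segregating site are skipped
    V = g.variants
    win = V["position"].to_numpy() // spec.window_bp
    key = V["chromosome"].to_numpy().astype(np.int64) * (2**40) + win
    order = np.argsort(key, kind="stable")
    causal: list = []
    start = 0
    keys_sorted = key[order]
    for end in np.r_[np.where(np.diff(keys_sorted) != 0)[0] + 1, len(order)]:
        block = order[start:end]
        block = block[eligible[block]]
        if block.size:
            causal.append(int(block[rng.integers(block.size)]))
        start = end
    causal = np.array(sorted(causal), dtype=np.int64)

    pj = p[causal]
    beta = rng.normal(0.0, np.sqrt((2.0 * pj * (1.0 - pj)) ** spec.alpha))

    n = g.n_samples
    G = np.zeros(n)
    for s in range(0, causal.size, 4096):  # chunked: causal sets can be large
        b = causal[s : s + 4096]
        X = g.dosages[:, b].astype(np.float64)
        miss = X < 0
        if miss.any():
            X[miss] = np.broadcast_to(2.0 * p[b], X.shape)[miss]
        G += X @ beta[s : s + 4096]
    G = G - G.mean()

    if spec.h2 > 0:
        gvar = G.var()
        if gvar == 0:
            raise ValueError("degenerate genetic score (zero variance)")
        G *= np.sqrt(spec.h2 / gvar)
        beta = beta * np.sqrt(spec.h2 / gvar)
    else:
        G = np.zeros(n)
        beta = np.zeros_like(beta)

    if spec.h2 < 1:
        eps = rng.standard_normal(n)
        eps -= eps.mean()
        if spec.h2 > 0:
            eps -= G * (eps @ G) / (G @ G)
        eps *= np.sqrt((1.0 - spec.h2) / eps.var())
    else:
        eps = np.zeros(n)

    y = G + eps
    realized = float(G.var() / y.var()) if y.var() > 0 else float("nan")
    return PhenotypeResult(
        values=y,
        causal_set=pd.DataFrame({"variant_index": causal, "beta": beta}),
        realized_h2=realized,
    )
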