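"""Genomic hotspots of informative-locus density.

Chromosomes are tiled into fixed windows (1 Mb by default); the all-SNP
counts per window are smoothed by a sticky hidden Markov model with Poisson
emissions, giving a position-varying background rate.  The expected
informative-locus rate in a window is the background rate thinned by the
global fraction of loci that are informative for the PC, and the hotspot
p-value is the Poisson upper tail of the observed informative count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn import hmm
from scipy.stats import poisson

__all__ = [
    "window_counts",
    "BackgroundHMM",
    "fit_background",
    "hotspot_pvalues",
    "poisson_tail_logp",
]

WINDOW_BP = 1_000_000


def window_counts(loci: pd.DataFrame, window_bp: int = WINDOW_BP,
                  locus_subset=None) -> pd.DataFrame:
    """Count loci per non-overlapping window of ``window_bp`` on each
    chromosome.  A locus at 1-based position p falls in window
    floor((p-1)/window_bp); the trailing partial window is kept.  Windows
    tile each chromosome from 0 through the last occupied window of the full
    locus table, so counts from a subset align with the background."""
    pos = loci["pos"].to_numpy()
    chrom = loci["chrom"].to_numpy()
    widx = (pos - 1) // window_bp
    rows = []
    for c in pd.unique(chrom):
        mask = chrom == c
        n_win = int(widx[mask].max()) + 1
        sub = mask if locus_subset is None else mask & locus_subset
        counts = np.bincount(widx[sub], minlength=n_win)[:n_win]
        for w in range(n_win):
            rows.append((c, w, w * window_bp, (w + 1) * window_bp, int(counts[w])))
    return pd.DataFrame(rows, columns=["chrom", "window", "start", "end", "count"])


@dataclass
class BackgroundHMM:
    """Fitted sticky Poisson HMM and posterior-weighted per-window rates."""

    state_rates: np.ndarray
    transmat: np.ndarray
    rates: pd.DataFrame  # chrom, window, rate


def fit_background(windows: pd.DataFrame, n_states: int = 10,
                   self_transition: float = 0.9, n_iter: int = 100,
                   tol: float = 1e-6, random_state: int = 0) -> BackgroundHMM:
    """Fit the position-varying background SNP rate.

    Hidden states are Poisson rates initialized at count quantiles with a
    sticky transition matrix (self-transition ``self_transition``, uniform
    off-diagonal); rates are refined by Baum-Welch and each window's
    background rate is the posterior-weighted state rate.  With a single
    state the model collapses to the Poisson MLE (the global mean count),
    computed analytically.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    counts = windows["count"].to_numpy()
    if counts.sum() == 0:
        raise ValueError("all window counts are zero; no background to fit")
    if n_states == 1:
        rates = windows[["chrom", "window"]].copy()
        rates["rate"] = counts.mean()
        return BackgroundHMM(np.array([counts.mean()]),
                             np.array([[1.0]]), rates)
    qs = np.linspace(0, 1, n_states + 2)[1:-1]
    lambdas = np.maximum(np.quantile(counts, qs), 1e-3)
    lambdas += np.arange(n_states) * 1e-6  # break exact ties between states
    off = (1.0 - self_transition) / (n_states - 1)
    transmat = np.full((n_states, n_states), off)
    np.fill_diagonal(transmat, self_transition)
    model = hmm.PoissonHMM(n_components=n_states, n_iter=n_iter, tol=tol,
                           random_state=random_state, params="l",
                           init_params="")
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.transmat_ = transmat
    model.lambdas_ = lambdas[:, None]
    x = counts[:, None]
    lengths = windows.groupby("chrom", sort=False).size().to_list()
    model.fit(x, lengths)
    post = model.predict_proba(x, lengths)
    rates = windows[["chrom", "window"]].copy()
    rates["rate"] = post @ model.lambdas_[:, 0]
    return BackgroundHMM(model.lambdas_[:, 0].copy(), model.transmat_.copy(), rates)


def poisson_tail_logp(observed: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log10 of the Poisson upper tail P(X >= observed), exact in log space
    (underflow-free down to magnitudes like 1e-50); observed = 0 gives p = 1."""
    observed = np.asarray(observed)
    lam = np.asarray(lam, dtype=np.float64)
    return poisson.logsf(observed - 1, lam) / np.log(10.0)


def hotspot_pvalues(informative_windows: pd.DataFrame, background: BackgroundHMM,
                    informative_fraction: float,
                    threshold: float = 1e-50) -> pd.DataFrame:
    """Hotspot scan of informative-locus counts against the thinned background.

    The expected informative rate in a window is the fitted background rate
    times the global fraction of loci informative for the PC; the p-value is
    the Poisson tail P(X >= observed).  Windows at or below ``threshold`` are
    flagged and adjacent flagged windows are merged into hotspot intervals
    (``interval_id``; -1 outside hotspots).  ``rescaled`` is observed over
    expected.
    """
    df = informative_windows.merge(background.rates, on=["chrom", "window"],
                                   validate="one_to_one")
    lam = df["rate"].to_numpy() * informative_fraction
    obs = df["count"].to_numpy()
    df["expected"] = lam
    df["log10_p"] = poisson_tail_logp(obs, lam)
    df["rescaled"] = obs / np.maximum(lam, 1e-300)
    df["hotspot"] = df["log10_p"] <= np.log10(threshold)
    interval = np.full(len(df), -1)
    current = -1
    prev_key = None
    for i, row in enumerate(df.itertuples(index=False)):
        if row.hotspot:
            key = (row.chrom, row.window - 1)
            if prev_key != key:
                current += 1
            interval[i] = current
            prev_key = (row.chrom, row.window)
        else:
            prev_key = None
    df["interval_id"] = interval
    return df
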