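"""Two-state (and K-state) Gaussian HMM segmentation of binned signal.

Domains are defined as maximal Viterbi runs of the "high signal" state of a
Gaussian-emission HMM trained by Baum-Welch on the normalized RPKM values.
Candidate state numbers are compared by AIC and BIC; the two-state model
(background vs high signal) is the working choice for domain calling.

hmmlearn provides the Baum-Welch / forward / Viterbi machinery; this module
owns masking and run-splitting (blacklist gaps carry no adjacency
information, so each valid-bin run is an independent sequence), quantile
initialization, restarts on degenerate fits, ascending-mean state
relabeling, model selection, consensus across replicates and JSON
serialization.
"""

from __future__ import annotations

import functools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM

from .core import (
    BinnedSignalTrack,
    DomainSet,
    GenomicInterval,
    intersect_intervals,
    merge_intervals,
)

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 500
N_RESTARTS = 5
SIGMA_FLOOR_FRACTION = 1e-3  # sigma floor as a fraction of the sample sigma


class DegenerateFitError(RuntimeError):
    """Baum-Welch collapsed a state (weight -> 0) on every restart."""


@dataclass
class HMMModel:
    """A fitted K-state Gaussian-emission HMM.

    States are sorted by ascending mean, so state K-1 is "high signal".
    """

    K: int
    means: np.ndarray        # (K,)
    sds: np.ndarray          # (K,)
    transmat: np.ndarray     # (K, K) row-stochastic
    startprob: np.ndarray    # (K,)
    log_likelihood: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        K = self.K
        if self.means.shape != (K,) or self.sds.shape != (K,):
            raise ValueError("means/sds must have shape (K,)")
        if self.transmat.shape != (K, K) or self.startprob.shape != (K,):
            raise ValueError("transmat/startprob shape mismatch")
        if np.any(self.sds <= 0):
            raise ValueError("state sds must be > 0")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("states must be sorted by ascending mean")

    @property
    def high_state(self) -> int:
        return self.K - 1

    def n_parameters(self) -> int:
        """Free parameters: K(K-1) transitions + (K-1) initial + 2K emission
        = K^2 + 2K - 1."""
        return self.K**2 + 2 * self.K - 1

    def to_hmmlearn(self) -> GaussianHMM:
        m = GaussianHMM(
            n_components=self.K, covariance_type="diag", init_params="", params=""
        )
        m.means_ = self.means.reshape(-1, 1)
        m.covars_ = (self.sds**2).reshape(-1, 1)
        m.transmat_ = self.transmat.copy()
        m.startprob_ = self.startprob.copy()
        return m

    def to_json(self, path: str | Path) -> None:
        data = {
            "K": self.K,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": self.log_likelihood,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            K=d["K"], means=d["means"], sds=d["sds"], transmat=d["transmat"],
            startprob=d["startprob"], log_likelihood=d["log_likelihood"],
            meta=d.get("meta", {}),
        )


class _FullHistoryMonitor(ConvergenceMonitor):
    """Records the complete per-iteration log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: List[float] = []

    def _reset(self):
        super()._reset()
        self.full_history = []

    def report(self, log_prob):
        self.full_history.append(log_prob)
        super().report(log_prob)


def _stack(sequences: Sequence[np.ndarray]):
    seqs = [np.asarray(s, dtype=float).reshape(-1, 1) for s in sequences if len(s)]
    if not seqs:
        raise ValueError("no non-empty sequences")
    return np.vstack(seqs), [len(s) for s in seqs]


def log_likelihood(model: HMMModel, sequences: Sequence[np.ndarray]) -> float:
    """Forward-algorithm log-likelihood, summed over independent sequences."""
    X, lengths = _stack(sequences)
    return float(model.to_hmmlearn().score(X, lengths))


def _relabel_ascending(means, sds, transmat, startprob):
    order = np.argsort(means)
    return (
        means[order],
        sds[order],
        transmat[np.ix_(order, order)],
        startprob[order],
    )


def fit_hmm(
    sequences: Sequence[np.ndarray],
    K: int,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_restarts: int = N_RESTARTS,
) -> HMMModel:
    """Baum-Welch fit of a K-state Gaussian HMM on valid-bin runs.

    Initialization is deterministic given the seed: means at the quantile
    midpoints (25th/75th percentile for K=2), sds at the sample sd, diagonal
    transition probability 0.95, uniform start. Restarts (with jittered
    means) are only used if a state collapses.

    The EM log-likelihood trace is checked to be non-decreasing at every
    iteration; a violation beyond numerical noise is a hard error.
    """
    X, lengths = _stack(sequences)
    x = X[:, 0]
    if len(np.unique(x)) < K:
        raise ValueError(f"need >= {K} distinct observed values to fit K={K}")
    sample_sd = float(np.std(x))
    if sample_sd == 0:
        raise ValueError("constant signal; nothing to segment")
    sigma_floor = SIGMA_FLOOR_FRACTION * sample_sd
    quantiles = (2 * np.arange(K) + 1) / (2 * K)
    base_means = np.quantile(x, quantiles)

    rng = np.random.default_rng(seed)
    last_error: Optional[Exception] = None
    for attempt in range(n_restarts):
        means0 = base_means.copy()
        if attempt > 0:
            means0 = means0 + rng.normal(0, 0.25 * sample_sd, size=K)
            means0.sort()
        m = GaussianHMM(
            n_components=K,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=max_iter,
            tol=tol,
            min_covar=sigma_floor**2,
            random_state=int(rng.integers(2**31 - 1)),
        )
        m.means_ = means0.reshape(-1, 1)
        m.covars_ = np.full((K, 1), sample_sd**2)
        m.transmat_ = np.full((K, K), 0.05 / max(K - 1, 1))
        np.fill_diagonal(m.transmat_, 0.95 if K > 1 else 1.0)
        m.startprob_ = np.full(K, 1.0 / K)
        m.monitor_ = _FullHistoryMonitor(m.tol, m.n_iter)
        try:
            m.fit(X, lengths)
        except Exception as exc:  # numerical blow-up counts as degenerate
            last_error = exc
            continue

        history = np.asarray(m.monitor_.full_history)
        slack = 1e-6 * max(1.0, abs(history[-1]))
        if np.any(np.diff(history) < -slack):
            raise RuntimeError(
                "Baum-Welch log-likelihood decreased between iterations"
            )

        params = (
            m.means_[:, 0], np.sqrt(m.covars_[:, 0, 0]), m.transmat_, m.startprob_
        )
        if not all(np.all(np.isfinite(p)) for p in params):
            last_error = DegenerateFitError("non-finite parameters")
            continue
        occupancy = m.predict_proba(X, lengths).sum(axis=0)
        if K > 1 and occupancy.min() < 1.0:
            last_error = DegenerateFitError(
                f"state occupancy {occupancy.min():.3g} < 1 observation"
            )
            continue

        means, sds, A, pi = _relabel_ascending(*params)
        sds = np.maximum(sds, sigma_floor)
        # renormalize exactly; hmmlearn rows are stochastic to float precision
        A = A / A.sum(axis=1, keepdims=True)
        pi = pi / pi.sum()
        model = HMMModel(
            K=K, means=means, sds=sds, transmat=A, startprob=pi,
            log_likelihood=float(history[-1]),
            meta={
                "iterations": int(len(history)),
                "tol": tol,
                "seed": seed,
                "restart": attempt,
                "sigma_floor": sigma_floor,
                "n_obs": int(len(x)),
                "lnl_history": [float(v) for v in history],
            },
        )
        logger.info(
            "fit_hmm: K=%d converged in %d iterations, lnL=%.3f (restart %d)",
            K, len(history), model.log_likelihood, attempt,
        )
        return model
    raise DegenerateFitError(
        f"all {n_restarts} restarts degenerate for K={K}: {last_error}"
    )


@dataclass
class ModelSelectionReport:
    """AIC/BIC comparison across candidate state numbers.

    AIC = 2 p_K - 2 lnL; BIC = p_K ln(n) - 2 lnL with n = total valid bins.
    """

    n: int
    entries: List[dict]                 # per K: K, log_likelihood, p, aic, bic
    models: Dict[int, HMMModel]
    failed: Dict[int, str] = field(default_factory=dict)

    @property
    def best_aic(self) -> int:
        return min(self.entries, key=lambda e: e["aic"])["K"]

    @property
    def best_bic(self) -> int:
        return min(self.entries, key=lambda e: e["bic"])["K"]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.entries)
        df["selected_aic"] = df["K"] == self.best_aic
        df["selected_bic"] = df["K"] == self.best_bic
        return df


def information_criteria(log_lik: float, n_params: int, n_obs: int) -> tuple:
    aic = 2 * n_params - 2 * log_lik
    bic = n_params * np.log(n_obs) - 2 * log_lik
    return aic, bic


def select_model(
    sequences: Sequence[np.ndarray],
    Ks: Sequence[int] = (2, 3, 4, 5),
    seed: int = 0,
    **fit_kwargs,
) -> ModelSelectionReport:
    """Fit each candidate K and score by AIC and BIC."""
    if not Ks:
        raise ValueError("Ks must be non-empty")
    X, _ = _stack(sequences)
    n = len(X)
    entries, models, failed = [], {}, {}
    for K in Ks:
        try:
            model = fit_hmm(sequences, K, seed=seed, **fit_kwargs)
        except Exception as exc:
            failed[K] = str(exc)
            logger.warning("select_model: K=%d failed: %s", K, exc)
            continue
        p = model.n_parameters()
        aic, bic = information_criteria(model.log_likelihood, p, n)
        entries.append(
            {"K": K, "log_likelihood": model.log_likelihood, "p": p,
             "n": n, "aic": aic, "bic": bic}
        )
        models[K] = model
    if not entries:
        raise DegenerateFitError(f"every candidate K failed: {failed}")
    return ModelSelectionReport(n=n, entries=entries, models=models, failed=failed)


def decode(
    model: HMMModel,
    track: BinnedSignalTrack,
    mark: str = "",
    sample: str = "",
    high_states: Optional[Sequence[int]] = None,
    label: str = "domain",
) -> DomainSet:
    """Viterbi-decode a track; maximal high-state runs become domains.

    Each valid-bin run is decoded independently (invalid bins break
    domains). By default only the top-mean state counts as "high"; for K>2
    any set of non-background states can be requested.
    """
    high = set(high_states) if high_states is not None else {model.high_state}
    if 0 in high:
        raise ValueError("the background (lowest-mean) state cannot be a domain state")
    # with several non-background states, runs are reported per state
    per_state = len(high) > 1
    hm = model.to_hmmlearn()
    b = track.bin_size
    intervals: List[GenomicInterval] = []
    for chrom in sorted(track.genome.chroms):
        L = track.genome[chrom]
        for start_bin, end_bin in track.valid_run_spans(chrom):
            obs = track.values[chrom][start_bin:end_bin].reshape(-1, 1)
            states = hm.predict(obs)
            def same_run(j: int, s: int) -> bool:
                return states[j] == s if per_state else states[j] in high

            i = 0
            while i < len(states):
                s = states[i]
                if s in high:
                    j = i
                    while j < len(states) and same_run(j, s):
                        j += 1
                    intervals.append(
                        GenomicInterval(
                            chrom,
                            (start_bin + i) * b,
                            min((start_bin + j) * b, L),
                            f"state_{s}" if per_state else label,
                        )
                    )
                    i = j
                else:
                    i += 1
    return DomainSet(
        mark=mark,
        sample=sample,
        intervals=intervals,
        provenance={"model_K": model.K, "high_states": sorted(high)},
    )


def consensus_domains(replicate_domains: Sequence[DomainSet]) -> DomainSet:
    """Regions shared by all replicates: base-pair intersection across the
    replicate domain sets, then bookended intervals merged (distance 0)."""
    if not replicate_domains:
        raise ValueError("need at least one replicate")
    marks = {d.mark for d in replicate_domains}
    if len(marks) > 1:
        raise ValueError(f"mixed marks in consensus: {sorted(marks)}")
    current = list(replicate_domains[0].intervals)
    for rep in replicate_domains[1:]:
        current = intersect_intervals(current, rep.intervals)
    merged = merge_intervals(current, merge_distance=0)
    merged = [
        GenomicInterval(iv.chrom, iv.start, iv.end, "domain") for iv in merged
    ]
    return DomainSet(
        mark=replicate_domains[0].mark,
        sample="consensus",
        intervals=merged,
        provenance={"n_replicates": len(replicate_domains)},
    )
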