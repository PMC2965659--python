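"""Exponential random graph models (ERGM / p*) with motif statistics.

The model places probability proportional to ``exp(sum_mu theta_mu *
g_mu(y))`` on directed graphs ``y``, where the statistics ``g_mu`` are
motif counts (arcs, asymmetric/mutual dyads, triad-census classes,
k-stars, cyclic triples).  No implicit edges term is added: the sign of a
coefficient is interpreted relative to the uniform random digraph with
arc probability 1/2, and a model contains exactly the statistics listed.

Sampling is single-arc-toggle Metropolis-Hastings driven by *change
statistics* (the exact difference each toggle makes to every statistic,
computed locally).  Fitting uses maximum pseudo-likelihood (logistic
regression of arc indicators on their change statistics) to initialize a
stochastic-approximation MCMC maximum-likelihood iteration that solves
the moment equation E_theta[g] = g_observed.  Standard errors come from
the estimated Fisher information (the covariance of sampled statistics).
The log-likelihood is estimated by bridge sampling along a path from
theta = 0, whose normalizer is analytic: log n(0) = N(N-1) ln 2.

Degeneracy — a fitted distribution that collapses onto a handful of
graphs so that sampled statistics no longer overlap the observed values —
is detected and flagged; residual deviance and AIC are then reported as
unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Any

import numpy as np
import statsmodels.api as sm
from scipy.special import logsumexp

from .graph import Graph
from .motifs import TRIAD_LABELS, _TRIAD_LOOKUP, count_motif

__all__ = [
    "ErgmModel",
    "ErgmFit",
    "ergm_statistics",
    "ergm_sample",
    "ergm_fit",
    "ergm_deviance",
    "ergm_gof",
    "exact_mle",
    "akaike_weights",
]

_KNOWN_SIMPLE = ("edges", "asym", "mutual", "cycle_3")


def _is_triad(label: str) -> bool:
    return label.removeprefix("triad_") in TRIAD_LABELS


def _validate_labels(labels: list[str]) -> None:
    if not labels:
        raise ValueError("statistics list must be nonempty")
    if len(set(labels)) != len(labels):
        raise ValueError("statistic labels must be unique")
    for lab in labels:
        if lab in _KNOWN_SIMPLE or _is_triad(lab):
            continue
        if lab.startswith(("instar_", "outstar_")) and lab.split("_")[1].isdigit():
            continue
        raise ValueError(f"unknown statistic label {lab!r}")


@dataclass
class ErgmModel:
    """Statistics and coefficients of an exponential random graph model."""

    statistics: list[str]
    theta: np.ndarray

    def __post_init__(self) -> None:
        _validate_labels(self.statistics)
        t = np.asarray(self.theta, dtype=float)
        if t.shape != (len(self.statistics),):
            raise ValueError("theta must have one entry per statistic")
        if not np.all(np.isfinite(t)):
            raise ValueError("theta must be finite")
        self.theta = t


def ergm_statistics(g: Graph, labels: list[str]) -> np.ndarray:
    """Vector of motif-statistic counts of a digraph."""
    _validate_labels(labels)
    return np.array([count_motif(g, lab) for lab in labels], dtype=float)


# ---------------------------------------------------------------------------
# change statistics


class _ChangeStats:
    """Exact statistic differences for single-arc toggles.

    ``delta(a, i, j)`` returns g(after toggle of arc i->j) - g(before),
    computed locally: dyad statistics from the reciprocal arc, star
    statistics from the endpoint degrees, triad statistics by
    reclassifying the N-2 triples that contain both endpoints.
    """

    def __init__(self, labels: list[str]):
        _validate_labels(labels)
        self.labels = labels
        self.triad_positions = [
            (pos, TRIAD_LABELS.index(lab.removeprefix("triad_")))
            for pos, lab in enumerate(labels)
            if _is_triad(lab)
        ]
        self.need_triads = bool(self.triad_positions)

    def delta(self, a: np.ndarray, i: int, j: int) -> np.ndarray:
        cur = int(a[i, j])
        sign = 1 - 2 * cur  # +1 when adding the arc, -1 when removing
        recip = int(a[j, i])
        out = np.zeros(len(self.labels))
        if self.need_triads:
            n = a.shape[0]
            w = np.delete(np.arange(n), [i, j])
            base = (
                recip << 1
                | a[i, w] << 2
                | a[w, i] << 3
                | a[j, w] << 4
                | a[w, j] << 5
            ).astype(np.int64)
            before = np.bincount(_TRIAD_LOOKUP[base | cur], minlength=16)
            after = np.bincount(_TRIAD_LOOKUP[base | (1 - cur)], minlength=16)
            tri_delta = after - before
        for pos, lab in enumerate(self.labels):
            if lab == "edges":
                out[pos] = sign
            elif lab == "mutual":
                out[pos] = sign * recip
            elif lab == "asym":
                out[pos] = sign * (1 - 2 * recip)
            elif lab == "cycle_3":
                out[pos] = sign * int(np.dot(a[j], a[:, i]))
            elif lab.startswith("instar_"):
                s = int(lab.split("_")[1])
                indeg = int(a[:, j].sum()) - cur  # in-degree without this arc
                out[pos] = sign * comb(indeg, s - 1)
            elif lab.startswith("outstar_"):
                s = int(lab.split("_")[1])
                outdeg = int(a[i].sum()) - cur
                out[pos] = sign * comb(outdeg, s - 1)
        for pos, tri_idx in self.triad_positions:
            out[pos] = tri_delta[tri_idx]
        return out


# ---------------------------------------------------------------------------
# Metropolis-Hastings sampler


def _run_chain(
    model: ErgmModel,
    start: np.ndarray,
    n_proposals: int,
    rng: np.random.Generator,
    record_every: int = 0,
    keep_graphs: bool = False,
) -> dict[str, Any]:
    """Single-arc-toggle MH chain; returns final state, statistic trace
    (one row per recorded state) and acceptance rate."""
    a = start.copy()
    n = a.shape[0]
    cs = _ChangeStats(model.statistics)
    theta = model.theta
    stats = ergm_statistics(Graph(a.copy(), directed=True), model.statistics)
    trace: list[np.ndarray] = []
    graphs: list[np.ndarray] = []
    accepted = 0
    for step in range(n_proposals):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        d = cs.delta(a, i, j)
        logr = float(theta @ d)
        if logr >= 0 or rng.random() < np.exp(logr):
            a[i, j] ^= 1
            stats = stats + d
            accepted += 1
        if record_every and (step + 1) % record_every == 0:
            trace.append(stats.copy())
            if keep_graphs:
                graphs.append(a.copy())
    return {
        "state": a,
        "trace": np.array(trace) if trace else np.empty((0, len(theta))),
        "graphs": graphs,
        "acceptance_rate": accepted / max(n_proposals, 1),
    }


def ergm_sample(
    model: ErgmModel,
    N: int,
    n_burn: int = 2000,
    n_keep: int = 100,
    thin: int = 100,
    seed: int | None = None,
    start: Graph | None = None,
) -> tuple[list[Graph], np.ndarray]:
    """Draw graphs from an ERGM by Metropolis-Hastings.

    Returns ``n_keep`` graphs recorded every ``thin`` proposals after
    ``n_burn`` burn-in proposals, together with the statistic trace (one
    row per kept graph) for diagnostics.
    """
    if N < 3:
        raise ValueError("sampling requires N >= 3")
    rng = np.random.default_rng(seed)
    a0 = start.adjacency.astype(np.int8).copy() if start is not None else np.zeros((N, N), np.int8)
    burn = _run_chain(model, a0, n_burn, rng)
    out = _run_chain(
        model, burn["state"], n_keep * thin, rng, record_every=thin, keep_graphs=True
    )
    graphs = [
        Graph(g, directed=True, provenance={"sampler": "ergm_mh", "seed": seed})
        for g in out["graphs"]
    ]
    return graphs, out["trace"]


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ErgmFit:
    model: ErgmModel
    std_errors: np.ndarray
    observed: np.ndarray
    loglik_estimate: float
    loglik_mc_error: float
    aic: float
    null_deviance: float
    residual_deviance: float
    explained_deviance: float
    df_total: int
    df_model: int
    degenerate: bool
    note: str
    seed: int | None
    diagnostics: dict[str, Any] = field(default_factory=dict)


def _mple(g: Graph, labels: list[str]) -> np.ndarray:
    """Maximum pseudo-likelihood estimate: logistic regression of arc
    indicators on their change statistics."""
    a = g.adjacency.astype(np.int8)
    n = a.shape[0]
    cs = _ChangeStats(labels)
    rows, ys = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = cs.delta(a, i, j)
            if a[i, j]:
                d = -d  # delta of toggling off = -(with - without)
            rows.append(d)
            ys.append(a[i, j])
    X = np.array(rows)
    y = np.array(ys)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        theta = np.asarray(res.params, dtype=float)
    except Exception:
        theta = np.zeros(len(labels))
    return np.clip(np.nan_to_num(theta), -10, 10)


def ergm_fit(
    g: Graph,
    labels: list[str],
    n_iterations: int = 10,
    samples_per_iteration: int = 10_000,
    thin: int = 10,
    seed: int | None = None,
    n_bridges: int = 10,
    bridge_samples: int = 1000,
    compute_loglik: bool = True,
) -> ErgmFit:
    """MCMC maximum-likelihood fit of an ERGM to an observed digraph.

    The default schedule is a desk-scale version of 10 iterations of 1e5
    sampled networks: 10 stochastic-approximation iterations, each using
    ``samples_per_iteration`` Metropolis proposals.  Pass larger values to
    restore the full scale.
    """
    if not g.directed or g.weighted:
        raise ValueError("ERGM fitting requires a directed unweighted graph")
    _validate_labels(labels)
    g_obs = ergm_statistics(g, labels)
    N = g.n_nodes
    M = N * (N - 1)
    maxima = {"edges": M, "mutual": M // 2, "asym": M // 2}
    for lab, val in zip(labels, g_obs):
        if val == 0:
            raise ValueError(f"observed statistic {lab!r} is zero (boundary); cannot fit")
        if lab in maxima and val >= maxima[lab]:
            raise ValueError(f"observed statistic {lab!r} is at its maximum (boundary)")
    rng = np.random.default_rng(seed)
    p = len(labels)
    theta = _mple(g, labels)
    a_obs = g.adjacency.astype(np.int8)
    burn = max(samples_per_iteration // 5, 200)
    keep = max((samples_per_iteration - burn) // thin, 50)

    last = None
    for it in range(n_iterations):
        model = ErgmModel(labels, theta)
        chain = _run_chain(model, a_obs, burn, rng)
        out = _run_chain(model, chain["state"], keep * thin, rng, record_every=thin)
        S = out["trace"]
        mean = S.mean(0)
        cov = np.cov(S.T) if p > 1 else np.array([[S.var(ddof=1)]])
        cov = np.atleast_2d(cov) + 1e-8 * np.eye(p)
        gain = 0.5 / (1.0 + it) ** 0.6
        step = gain * np.linalg.solve(cov, g_obs - mean)
        norm = np.linalg.norm(step)
        if norm > 0.5:  # trust region: keep stochastic updates stable
            step *= 0.5 / norm
        theta = theta + step
        last = {"S": S, "mean": mean, "cov": cov, "acc": out["acceptance_rate"]}

    model = ErgmModel(labels, theta)
    # final sample at theta-hat for SEs and degeneracy diagnostics
    chain = _run_chain(model, a_obs, burn, rng)
    out = _run_chain(model, chain["state"], keep * thin, rng, record_every=thin)
    S = out["trace"]
    cov = np.atleast_2d(np.cov(S.T)) + 1e-8 * np.eye(p)
    se = np.sqrt(np.diag(np.linalg.inv(cov)))

    degenerate = False
    notes = []
    for m, lab in enumerate(labels):
        lo, hi = S[:, m].min(), S[:, m].max()
        sd = S[:, m].std(ddof=1)
        if not lo <= g_obs[m] <= hi:
            degenerate = True
            notes.append(
                f"sampled {lab} in [{lo:.0f}, {hi:.0f}] does not cover observed {g_obs[m]:.0f}"
            )
        elif sd == 0 and S[:, m].mean() != g_obs[m]:
            degenerate = True
            notes.append(f"sampled {lab} collapsed to a single value")
    note = "model degeneracy: " + "; ".join(notes) if degenerate else "ok"

    null_dev = 2.0 * M * np.log(2.0)
    if degenerate or not compute_loglik:
        loglik, mc_err = float("nan"), float("nan")
        aic = res_dev = exp_dev = float("nan")
    else:
        loglik, mc_err = _bridge_loglik(
            model, g_obs, a_obs, rng, n_bridges, bridge_samples, thin
        )
        res_dev = -2.0 * loglik
        exp_dev = null_dev - res_dev
        aic = 2.0 * p - 2.0 * loglik
    return ErgmFit(
        model=model,
        std_errors=se,
        observed=g_obs,
        loglik_estimate=loglik,
        loglik_mc_error=mc_err,
        aic=aic,
        null_deviance=float(null_dev),
        residual_deviance=float(res_dev),
        explained_deviance=float(exp_dev),
        df_total=M,
        df_model=p,
        degenerate=degenerate,
        note=note,
        seed=seed,
        diagnostics={
            "acceptance_rate": out["acceptance_rate"],
            "sampled_mean": S.mean(0),
            "sampled_sd": S.std(0, ddof=1),
            "mple": _mple(g, labels),
        },
    )


def _bridge_loglik(
    model: ErgmModel,
    g_obs: np.ndarray,
    a_obs: np.ndarray,
    rng: np.random.Generator,
    n_bridges: int,
    bridge_samples: int,
    thin: int,
) -> tuple[float, float]:
    """log-likelihood by path/bridge sampling from theta = 0.

    log n(theta) - log n(0) = sum_t log E_{theta_t}[exp(dtheta . g)]
    along theta_t = (t / J) theta; log n(0) = M ln 2 is analytic.
    """
    N = a_obs.shape[0]
    M = N * (N - 1)
    theta = model.theta
    log_n = M * np.log(2.0)
    var_total = 0.0
    burn = max(bridge_samples * thin // 5, 200)
    for t in range(n_bridges):
        theta_t = theta * (t / n_bridges)
        dtheta = theta / n_bridges
        m_t = ErgmModel(model.statistics, theta_t)
        start = a_obs if t == 0 else state
        chain = _run_chain(m_t, start, burn, rng)
        out = _run_chain(m_t, chain["state"], bridge_samples * thin, rng, record_every=thin)
        state = out["state"]
        w = out["trace"] @ dtheta
        log_mean = float(logsumexp(w) - np.log(len(w)))
        log_n += log_mean
        # delta-method variance of log-mean-exp
        ww = np.exp(w - w.max())
        var_total += float(ww.var(ddof=1) / (len(ww) * ww.mean() ** 2))
    loglik = float(theta @ g_obs - log_n)
    return loglik, float(np.sqrt(var_total))


def null_deviance(N: int) -> tuple[float, int]:
    """Null deviance and total degrees of freedom for an N-node digraph.

    The null model assigns probability 1/2 to each of the N(N-1) possible
    arcs: deviance = 2 N(N-1) ln 2, df = N(N-1)."""
    M = N * (N - 1)
    return 2.0 * M * float(np.log(2.0)), M


def ergm_deviance(fit: ErgmFit) -> tuple[float, float, float, float]:
    """(null deviance, residual deviance, explained deviance, AIC).

    The null model assigns probability 1/2 to each of the N(N-1) possible
    arcs, so the null deviance is 2 N(N-1) ln 2 regardless of the data.
    Residual quantities are unavailable (NaN) for degenerate fits.
    """
    return (
        fit.null_deviance,
        fit.residual_deviance,
        fit.explained_deviance,
        fit.aic,
    )


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Akaike weights w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    aics = np.asarray(aics, dtype=float)
    d = aics - np.nanmin(aics)
    w = np.exp(-d / 2.0)
    return w / np.nansum(w)


# ---------------------------------------------------------------------------
# exact enumeration (small N) — used as an independent cross-check


def exact_mle(g: Graph, labels: list[str]) -> np.ndarray:
    """Exact MLE by full enumeration of all digraphs on N nodes (N <= 4)."""
    from scipy.optimize import minimize

    N = g.n_nodes
    M = N * (N - 1)
    if M > 12:
        raise ValueError("exact enumeration is limited to N <= 4")
    pairs = [(i, j) for i in range(N) for j in range(N) if i != j]
    stats = np.empty((2**M, len(labels)))
    for code in range(2**M):
        a = np.zeros((N, N), dtype=np.int8)
        for b, (i, j) in enumerate(pairs):
            if code >> b & 1:
                a[i, j] = 1
        stats[code] = ergm_statistics(Graph(a, directed=True), labels)
    g_obs = ergm_statistics(g, labels)

    def negloglik(theta: np.ndarray) -> float:
        return float(logsumexp(stats @ theta) - theta @ g_obs)

    res = minimize(negloglik, np.zeros(len(labels)), method="BFGS")
    return np.asarray(res.x)


# ---------------------------------------------------------------------------
# goodness of fit


def ergm_gof(
    fit: ErgmFit,
    g: Graph,
    n_sim: int = 100,
    seed: int | None = None,
    thin_proposals: int | None = None,
) -> dict[str, Any]:
    """Simulate networks at the fitted coefficients and compare their triad
    census, in/out-degree distributions and modeled statistics with the
    observed network (95% simulation envelopes + inside-envelope flags)."""
    if fit.degenerate:
        raise ValueError("goodness of fit is unavailable for a degenerate fit")
    from .motifs import triad_census

    N = g.n_nodes
    thin = thin_proposals or 2 * N * (N - 1)
    graphs, trace = ergm_sample(
        fit.model, N, n_burn=5 * thin, n_keep=n_sim, thin=thin, seed=seed, start=g
    )
    tri = np.array([triad_census(s).as_vector() for s in graphs])
    indeg = np.array([np.bincount(s.adjacency.sum(0), minlength=N) for s in graphs])
    outdeg = np.array([np.bincount(s.adjacency.sum(1), minlength=N) for s in graphs])
    obs_tri = triad_census(g).as_vector()
    obs_in = np.bincount(g.adjacency.sum(0), minlength=N)
    obs_out = np.bincount(g.adjacency.sum(1), minlength=N)

    def envelope(sim: np.ndarray, obs: np.ndarray) -> dict[str, Any]:
        lo, hi = np.percentile(sim, [2.5, 97.5], axis=0)
        return {
            "simulated_mean": sim.mean(0),
            "simulated_sd": sim.std(0, ddof=1),
            "lo": lo,
            "hi": hi,
            "observed": obs,
            "inside": (lo <= obs) & (obs <= hi),
        }

    return {
        "triad_census": envelope(tri, obs_tri),
        "in_degree": envelope(indeg, obs_in),
        "out_degree": envelope(outdeg, obs_out),
        "statistics": envelope(trace, fit.observed),
        "n_sim": n_sim,
    }
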