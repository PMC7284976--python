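"""Supervised Bayesian admixture inference on ploidy-100 genotypes.

A sample is modelled as a single admixed individual whose allele copies
are drawn from K predefined population groups: with mixture proportions
q ~ Dirichlet(alpha) and per-group allele frequencies
p_k,l ~ Dirichlet(lambda + n_k,l), each copy at locus l carries allele
j with probability sum_k q_k p_k,l,j.  The frequencies are informed
*only* by the labeled learning strains (the counts n), never by the
test sample — the supervised training that associates alleles with
population groups.  Inference is by Gibbs sampling over (p, z, q),
where z assigns each allele copy to a group of origin.

Because copies of the same allele at the same locus are exchangeable,
the z-update is drawn as one multinomial per distinct (locus, allele)
pair, which makes a sweep cheap even at ploidy 100.

A *run* re-classifies every learning strain (leaving its own copies
out of the counts) and is accepted only when at least 80% are assigned
back to their labeled group; results aggregate over a fixed number of
accepted runs (default 20) started from consecutive seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .profiles import MISSING, PloidyProfile
from .scheme import MLSTScheme

__all__ = [
    "MCMCConfig",
    "PopulationAlleleFrequencies",
    "GibbsResult",
    "AdmixtureRun",
    "AdmixtureResult",
    "count_learning_alleles",
    "gibbs_infer",
    "classify_learning",
    "run_mgmlst",
    "merge_groups",
]


@dataclass
class MCMCConfig:
    """Run configuration for the Gibbs sampler.

    Defaults mirror the method's standard operating point: a 25,000-sweep
    burn-in followed by 125,000 retained sweeps, at least 20 accepted
    runs, K set by the learning set.  ``alpha`` is the Dirichlet
    concentration on q (None -> fixed 1/K; ``alpha_mode="metropolis"``
    instead samples a common alpha with a uniform prior on (0, 10]).
    ``lambda_`` is the Dirichlet pseudocount on allele frequencies.
    ``sample_frequencies=False`` freezes p at its posterior mean — a
    fast mode for tests and oracle comparisons.  Classification of
    learning strains (the run-acceptance check) uses its own, shorter
    chain lengths.
    """

    burn_in: int = 25_000
    iterations: int = 125_000
    n_runs: int = 20
    K: int | None = None
    alpha: float | None = None
    alpha_mode: Literal["fixed", "metropolis"] = "fixed"
    lambda_: float = 1.0
    seed: int = 0
    sample_frequencies: bool = True
    accept_threshold: float = 0.8
    classify_burn_in: int = 100
    classify_iterations: int = 400
    max_attempts: int = 100
    aggregate: Literal["mean", "median"] = "mean"

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.iterations <= 0:
            raise ValueError("burn_in must be >= 0 and iterations > 0")
        if self.iterations < 100:
            warnings.warn("iterations < 100: diagnostics will be unreliable")


@dataclass
class PopulationAlleleFrequencies:
    """Learning-set allele-copy counts per (group, locus, allele).

    ``counts[l]`` is a (K, J_l) array of copy counts; ``allele_index[l]``
    maps catalogue allele IDs to columns.  Adding the pseudocount
    ``lambda_`` gives the Dirichlet posterior over each group's allele
    frequencies at each locus.
    """

    groups: list[str]
    loci: list[str]
    counts: list[np.ndarray]
    allele_index: list[dict[int, int]]
    lambda_: float = 1.0

    @property
    def K(self) -> int:
        return len(self.groups)

    def posterior_mean(self) -> list[np.ndarray]:
        """Posterior-mean allele frequencies per locus, rows normalized."""
        out = []
        for c in self.counts:
            a = c + self.lambda_
            out.append(a / a.sum(axis=1, keepdims=True))
        return out


@dataclass
class GibbsResult:
    """Posterior-mean admixture proportions with Monte-Carlo diagnostics."""

    groups: list[str]
    q_mean: np.ndarray
    q_se: np.ndarray
    n_sweeps: int

    def as_dict(self) -> dict[str, float]:
        return {g: float(v) for g, v in zip(self.groups, self.q_mean)}


@dataclass
class AdmixtureRun:
    """One MCMC run: per-sample q plus the learning-set acceptance check."""

    seed: int
    q: dict[str, np.ndarray]
    q_se: dict[str, np.ndarray]
    learning_accuracy: float
    accepted: bool


@dataclass
class AdmixtureResult:
    """Aggregated proportions over accepted runs, raw and merged."""

    groups: list[str]
    reporting_groups: list[str]
    q_mean: dict[str, np.ndarray]
    q_se: dict[str, np.ndarray]
    q_merged: dict[str, np.ndarray]
    n_runs_used: int
    runs: list[AdmixtureRun] = field(default_factory=list)


# ---------------------------------------------------------------------------
# learning counts
# ---------------------------------------------------------------------------


def count_learning_alleles(
    learning: Sequence[PloidyProfile],
    scheme: MLSTScheme | None = None,
    lambda_: float = 1.0,
) -> PopulationAlleleFrequencies:
    """Tally learning allele copies into per-(group, locus, allele) counts.

    Groups are ordered by first appearance in ``learning``.  The allele
    universe per locus is the scheme catalogue when ``scheme`` is given,
    otherwise the union of alleles observed in the learning set.
    Missing-data codes contribute to no count.
    """
    if not learning:
        raise ValueError("empty learning set")
    groups: list[str] = []
    for prof in learning:
        if prof.group is None:
            raise ValueError(f"learning profile {prof.sample!r} has no group label")
        if prof.group not in groups:
            groups.append(prof.group)
    loci = list(learning[0].copies)
    allele_index: list[dict[int, int]] = []
    for l in loci:
        if scheme is not None:
            ids = sorted(scheme.locus(l).alleles)
        else:
            ids = sorted(
                {int(a) for prof in learning for a in prof.copies[l] if a != MISSING}
            )
        allele_index.append({aid: j for j, aid in enumerate(ids)})
    counts = [np.zeros((len(groups), len(idx)), dtype=np.float64)
              for idx in allele_index]
    gidx = {g: k for k, g in enumerate(groups)}
    for prof in learning:
        k = gidx[prof.group]
        for li, l in enumerate(loci):
            vals, cnts = np.unique(prof.copies[l], return_counts=True)
            for v, c in zip(vals, cnts):
                if v == MISSING:
                    continue
                j = allele_index[li].get(int(v))
                if j is None:
                    raise ValueError(
                        f"learning profile {prof.sample!r}: allele {int(v)} at "
                        f"locus {l!r} is not in the scheme catalogue"
                    )
                counts[li][k, j] += c
    empty = [g for g in groups if not any(counts[li][gidx[g]].sum() for li in range(len(loci)))]
    if empty:
        raise ValueError(f"groups with no allele copies: {empty}")
    return PopulationAlleleFrequencies(
        groups=groups, loci=loci, counts=counts,
        allele_index=allele_index, lambda_=lambda_,
    )


# ---------------------------------------------------------------------------
# Gibbs core
# ---------------------------------------------------------------------------


def _sample_entries(
    sample: PloidyProfile, freqs: PopulationAlleleFrequencies
) -> list[tuple[int, int, int]]:
    """Collapse a ploidy profile to (locus_index, allele_column, count)."""
    entries = []
    for li, l in enumerate(freqs.loci):
        if l not in sample.copies:
            raise ValueError(f"sample {sample.sample!r} lacks locus {l!r}")
        vals, cnts = np.unique(sample.copies[l], return_counts=True)
        for v, c in zip(vals, cnts):
            if v == MISSING:
                continue
            j = freqs.allele_index[li].get(int(v))
            if j is None:
                raise ValueError(
                    f"sample {sample.sample!r}: allele {int(v)} at locus {l!r} "
                    "is not in the allele universe"
                )
            entries.append((li, j, int(c)))
    return entries


def _gibbs(
    entries: Sequence[tuple[int, int, int]],
    freqs: PopulationAlleleFrequencies,
    cfg: MCMCConfig,
    rng: np.random.Generator,
    burn_in: int | None = None,
    iterations: int | None = None,
    counts_override: Sequence[np.ndarray] | None = None,
) -> GibbsResult:
    """Run one Gibbs chain; returns the posterior mean of q with MC SE.

    ``counts_override`` substitutes modified learning counts (used for
    leave-own-copies-out classification).
    """
    burn = cfg.burn_in if burn_in is None else burn_in
    iters = cfg.iterations if iterations is None else iterations
    K = freqs.K
    counts = counts_override if counts_override is not None else freqs.counts

    # flatten loci into one (K, Jtot) shape matrix for a single gamma draw
    widths = [c.shape[1] for c in counts]
    offsets = np.concatenate([[0], np.cumsum(widths)[:-1]]).astype(np.intp)
    shape_mat = np.concatenate(counts, axis=1) + cfg.lambda_
    gcols = [int(offsets[li] + j) for li, j, _ in entries]
    gcounts = [c for _, _, c in entries]
    glocus = [li for li, _, _ in entries]

    if not cfg.sample_frequencies:
        P = shape_mat / np.add.reduceat(shape_mat, offsets, axis=1).repeat(widths, axis=1)

    alpha0 = cfg.alpha if cfg.alpha is not None else 1.0 / K
    alpha = float(alpha0)
    q = np.full(K, 1.0 / K)

    n_retained = 0
    q_sum = np.zeros(K)
    n_batches = 20
    batch_size = max(1, iters // n_batches)
    batch_sums: list[np.ndarray] = []
    cur_batch = np.zeros(K)
    cur_n = 0

    for sweep in range(burn + iters):
        if cfg.sample_frequencies:
            G = rng.gamma(shape_mat)
            S = np.add.reduceat(G, offsets, axis=1)
        m = np.zeros(K)
        for col, c, li in zip(gcols, gcounts, glocus):
            if cfg.sample_frequencies:
                w = q * G[:, col] / S[:, li]
            else:
                w = q * P[:, col]
            tot = w.sum()
            if tot <= 0:
                raise ValueError(
                    "zero-likelihood allele copy: the sample carries an allele "
                    "with no frequency support in any group (lambda_ = 0?)"
                )
            m += rng.multinomial(c, w / tot)
        if cfg.alpha_mode == "metropolis":
            alpha = _update_alpha(alpha, q, rng)
        q = rng.dirichlet(np.full(K, alpha) + m)
        if sweep >= burn:
            q_sum += q
            cur_batch += q
            cur_n += 1
            n_retained += 1
            if cur_n == batch_size:
                batch_sums.append(cur_batch / cur_n)
                cur_batch = np.zeros(K)
                cur_n = 0
    if cur_n > 0:
        batch_sums.append(cur_batch / cur_n)
    q_mean = q_sum / n_retained
    if len(batch_sums) > 1:
        bm = np.vstack(batch_sums)
        q_se = bm.std(axis=0, ddof=1) / np.sqrt(bm.shape[0])
    else:
        q_se = np.full(K, np.nan)
    return GibbsResult(groups=list(freqs.groups), q_mean=q_mean, q_se=q_se,
                       n_sweeps=n_retained)


def _update_alpha(alpha: float, q: np.ndarray, rng: np.random.Generator,
                  sd: float = 0.25) -> float:
    """Metropolis step for a common alpha, uniform prior on (0, 10]."""
    prop = rng.normal(alpha, sd)
    if prop <= 0 or prop > 10:
        return alpha
    K = q.shape[0]
    from scipy.special import gammaln

    def logp(a: float) -> float:
        return gammaln(K * a) - K * gammaln(a) + (a - 1) * np.sum(np.log(q + 1e-300))

    if np.log(rng.uniform()) < logp(prop) - logp(alpha):
        return prop
    return alpha


def gibbs_infer(
    sample: PloidyProfile,
    freqs: PopulationAlleleFrequencies,
    cfg: MCMCConfig,
    rng: np.random.Generator | None = None,
) -> GibbsResult:
    """Infer a sample's admixture proportions q by Gibbs sampling.

    Returns the posterior mean of q over retained sweeps with a
    batch-means Monte-Carlo standard error per component.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    entries = _sample_entries(sample, freqs)
    if not entries:
        raise ValueError(f"sample {sample.sample!r} has no non-missing allele copies")
    return _gibbs(entries, freqs, cfg, rng)


# ---------------------------------------------------------------------------
# run acceptance and aggregation
# ---------------------------------------------------------------------------


def classify_learning(
    freqs: PopulationAlleleFrequencies,
    learning: Sequence[PloidyProfile],
    cfg: MCMCConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Re-classify each learning strain and return the fraction correct.

    Each strain is re-inferred as if it were a test sample, with its own
    copies left out of its group's counts; it is correct when the argmax
    of its inferred q equals its label.  A run is accepted when accuracy
    is at least 0.8 — the strict complement of "more than 20%
    misassigned".
    """
    if not learning:
        raise ValueError("empty learning set")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gidx = {g: k for k, g in enumerate(freqs.groups)}
    correct = 0
    for prof in learning:
        k = gidx[prof.group]
        entries = _sample_entries(prof, freqs)
        override = [c.copy() for c in freqs.counts]
        for li, j, c in entries:
            override[li][k, j] = max(0.0, override[li][k, j] - c)
        res = _gibbs(
            entries, freqs, cfg, rng,
            burn_in=cfg.classify_burn_in,
            iterations=cfg.classify_iterations,
            counts_override=override,
        )
        if int(np.argmax(res.q_mean)) == k:
            correct += 1
    return correct / len(learning)


def merge_groups(
    q: Mapping[str, float], merge_map: Mapping[str, str]
) -> dict[str, float]:
    """Fold population-group proportions into reporting groups.

    Every group in ``q`` must appear in ``merge_map``; reporting values
    are sums of their member groups, so the simplex is preserved.
    """
    out: dict[str, float] = {}
    for g, v in q.items():
        if g not in merge_map:
            raise KeyError(f"group {g!r} missing from merge map")
        out[merge_map[g]] = out.get(merge_map[g], 0.0) + float(v)
    return out


def _execute_attempt(
    seed: int,
    samples: Sequence[PloidyProfile],
    learning: Sequence[PloidyProfile],
    freqs: PopulationAlleleFrequencies,
    cfg: MCMCConfig,
) -> AdmixtureRun:
    """One independent run: acceptance check, then per-sample inference."""
    rng = np.random.default_rng(seed)
    accuracy = classify_learning(freqs, learning, cfg, rng)
    ok = accuracy >= cfg.accept_threshold
    q: dict[str, np.ndarray] = {}
    q_se: dict[str, np.ndarray] = {}
    if ok:
        for sample in samples:
            res = gibbs_infer(sample, freqs, cfg, rng)
            q[sample.sample] = res.q_mean
            q_se[sample.sample] = res.q_se
    return AdmixtureRun(seed=seed, q=q, q_se=q_se,
                        learning_accuracy=accuracy, accepted=ok)


def run_mgmlst(
    samples: Sequence[PloidyProfile],
    learning: Sequence[PloidyProfile],
    scheme: MLSTScheme,
    cfg: MCMCConfig,
    n_jobs: int = 1,
) -> AdmixtureResult:
    """Full inference: repeated accepted runs, aggregated and merged.

    Runs are launched with seeds ``cfg.seed + i`` until ``cfg.n_runs``
    pass the learning-set acceptance check (at most ``cfg.max_attempts``
    attempts, then an error with per-run diagnostics).  Per-sample q is
    the arithmetic mean (or median) of accepted runs; merged proportions
    sum population groups into reporting groups via the scheme's merge
    map.

    ``n_jobs > 1`` executes independent runs in parallel worker
    processes; each run is seeded by its attempt index, so the result
    is invariant to the worker count.
    """
    if not samples:
        raise ValueError("no samples to infer")
    freqs = count_learning_alleles(learning, scheme, lambda_=cfg.lambda_)
    if cfg.K is not None and cfg.K != freqs.K:
        raise ValueError(
            f"cfg.K = {cfg.K} does not match the {freqs.K} learning-set groups"
        )
    runs: list[AdmixtureRun] = []
    accepted: list[AdmixtureRun] = []
    attempt = 0
    while len(accepted) < cfg.n_runs and attempt < cfg.max_attempts:
        batch = 1 if n_jobs <= 1 else min(
            max(n_jobs, cfg.n_runs - len(accepted)),
            cfg.max_attempts - attempt,
        )
        seeds = [cfg.seed + attempt + i for i in range(batch)]
        if n_jobs <= 1 or batch == 1:
            batch_runs = [
                _execute_attempt(s, samples, learning, freqs, cfg) for s in seeds
            ]
        else:
            from concurrent.futures import ProcessPoolExecutor

            with ProcessPoolExecutor(max_workers=n_jobs) as pool:
                batch_runs = list(
                    pool.map(
                        _execute_attempt,
                        seeds,
                        [samples] * batch,
                        [learning] * batch,
                        [freqs] * batch,
                        [cfg] * batch,
                    )
                )
        for run in batch_runs:
            runs.append(run)
            if run.accepted and len(accepted) < cfg.n_runs:
                accepted.append(run)
        attempt += batch
    if len(accepted) < cfg.n_runs:
        diag = [
            {"seed": r.seed, "learning_accuracy": r.learning_accuracy,
             "accepted": r.accepted}
            for r in runs
        ]
        raise RuntimeError(
            f"only {len(accepted)} of the required {cfg.n_runs} runs were "
            f"accepted in {cfg.max_attempts} attempts; diagnostics: {diag}"
        )

    merge_total = {g: scheme.reporting_group(g) for g in freqs.groups}
    reporting: list[str] = []
    for g in freqs.groups:
        rg = merge_total[g]
        if rg not in reporting:
            reporting.append(rg)

    q_mean: dict[str, np.ndarray] = {}
    q_se_out: dict[str, np.ndarray] = {}
    q_merged: dict[str, np.ndarray] = {}
    n = len(accepted)
    for sample in samples:
        stack = np.vstack([r.q[sample.sample] for r in accepted])
        if cfg.aggregate == "median":
            mean = np.median(stack, axis=0)
            mean = mean / mean.sum()
        else:
            mean = stack.mean(axis=0)
        within = np.vstack([r.q_se[sample.sample] for r in accepted])
        between_var = stack.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
        se = np.sqrt(between_var / n + np.nanmean(within**2, axis=0) / n)
        q_mean[sample.sample] = mean
        q_se_out[sample.sample] = se
        merged = merge_groups(dict(zip(freqs.groups, mean)), merge_total)
        q_merged[sample.sample] = np.array([merged.get(rg, 0.0) for rg in reporting])
    return AdmixtureResult(
        groups=list(freqs.groups),
        reporting_groups=reporting,
        q_mean=q_mean,
        q_se=q_se_out,
        q_merged=q_merged,
        n_runs_used=n,
        runs=runs,
    )
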