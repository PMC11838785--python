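"""The Stroop color-naming task on a pair of coupled maps.

A trial presents a target color to the semantic map at full strength and,
depending on the condition, a distractor word to the lexical map at
strength ``r_lex`` (congruent: distractor = target; incongruent:
distractor != target; no-input: nothing).  Each time step both maps settle
one lateral update, semantic activation is routed into the lexical map
through the associative weights with gain ``gamma``, and the lexical map's
readout entropy is checked: once it drops below the threshold (1 bit) the
maximum-likelihood color is emitted and the step count is the response
time.  If the step cap is hit, naming fails.

The full factorial experiment runs all 16 congruent + 16 no-input +
240 incongruent cases (272 trials); trials are deterministic given the
trained model and parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .associative import HebbianAssociator
from .errors import DataError, ParameterError
from .lateral_som import ActivationState, LateralSOM, max_likelihood_response
from .stimuli import ColorLexicon, default_lexicon, incongruent_pairs

__all__ = [
    "CONDITIONS",
    "ConditionSummary",
    "StroopModel",
    "TrialResult",
    "TrialSpec",
    "rt_contrast_test",
    "run_factorial",
    "run_trial",
    "run_trials_batch",
    "summarize",
]

CONDITIONS = ("congruent", "no_input", "incongruent")


@dataclass(frozen=True)
class TrialSpec:
    """One Stroop trial: condition, stimuli, and routing parameters."""

    condition: str
    target: str
    distractor: str | None = None
    r_lex: float = 0.45
    gamma: float = 0.05
    entropy_threshold: float = 1.0
    max_steps: int = 500

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.condition == "congruent" and self.distractor != self.target:
            raise ParameterError("congruent trials require distractor == target")
        if self.condition == "incongruent" and (
                self.distractor is None or self.distractor == self.target):
            raise ParameterError("incongruent trials require a distinct distractor")
        if self.condition == "no_input" and self.distractor is not None:
            raise ParameterError("no_input trials take no distractor")
        if not (0.0 <= self.r_lex <= 1.0):
            raise ParameterError("r_lex must lie in [0, 1]")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be positive")


@dataclass
class TrialResult:
    """Outcome of one trial.

    ``steps`` is the response time in settle steps; for failed trials it
    equals the step cap and ``output`` is ``None``.  ``entropy_trace`` holds
    the lexical readout entropy at every step taken.  ``snapshots``, when
    recording is enabled, holds (t, semantic activation, lexical activation)
    triples for every step including t = 0.
    """

    spec: TrialSpec
    output: str | None
    correct: bool
    steps: int
    converged: bool
    entropy_trace: list[float] = field(default_factory=list)
    snapshots: list | None = None


def run_trial(sem_map: LateralSOM, lex_map: LateralSOM,
              assoc: HebbianAssociator, lexicon: ColorLexicon,
              spec: TrialSpec, record_snapshots: bool = False) -> TrialResult:
    """Run one Stroop trial and return its :class:`TrialResult`.

    Per iteration: settle both maps one step, transfer semantic activation
    to the lexical map, then check the lexical readout entropy against the
    threshold (the criterion sees post-transfer activation).
    """
    target_rgb = lexicon.rgb(spec.target)  # raises DataError if unknown
    sem_state = sem_map.initial_state(target_rgb, scale=1.0)
    if spec.condition == "no_input":
        # Zero lexical input; entropy is maximal until routed activation
        # arrives, so the map cannot respond spuriously at t = 0.
        lex_state = ActivationState(np.zeros(lex_map.n_units_))
    else:
        lex_state = lex_map.initial_state(
            lexicon.lexical_vector(spec.distractor), scale=spec.r_lex)

    snapshots = None
    if record_snapshots:
        snapshots = [(0, sem_state.activation.copy(), lex_state.activation.copy())]

    output, converged, steps = None, False, spec.max_steps
    trace: list[float] = []
    for t in range(1, spec.max_steps + 1):
        sem_map.settle(sem_state)
        lex_map.settle(lex_state)
        assoc.transfer(sem_state, lex_state, gamma=spec.gamma)
        h = lex_map.readout_entropy(lex_state.activation)
        trace.append(h)
        if record_snapshots:
            snapshots.append((t, sem_state.activation.copy(),
                              lex_state.activation.copy()))
        if h < spec.entropy_threshold:
            output = max_likelihood_response(
                lex_map.likelihood(lex_state.activation), lex_map.labels_)
            converged, steps = True, t
            break

    correct = converged and output == spec.target
    return TrialResult(spec=spec, output=output, correct=correct, steps=steps,
                       converged=converged, entropy_trace=trace,
                       snapshots=snapshots)


def _factorial_specs(lexicon: ColorLexicon, r_lex: float, gamma: float,
                     entropy_threshold: float, max_steps: int):
    common = dict(r_lex=r_lex, gamma=gamma,
                  entropy_threshold=entropy_threshold, max_steps=max_steps)
    specs = [TrialSpec("congruent", name, name, **common)
             for name in lexicon.labels]
    specs += [TrialSpec("no_input", name, None, **common)
              for name in lexicon.labels]
    specs += [TrialSpec("incongruent", t, d, **common)
              for t, d in incongruent_pairs(lexicon)]
    return specs


def run_trials_batch(sem_map, lex_map, assoc, lexicon, specs,
                     keep_traces: bool = False) -> list[TrialResult]:
    """Run many independent trials with batched linear algebra.

    Equivalent to calling :func:`run_trial` per spec (the same update
    sequence is applied to every trial; trials are independent, so the
    only difference is floating-point summation order inside the matrix
    products).  All specs must share ``gamma``, ``entropy_threshold`` and
    ``max_steps``.  Entropy traces are dropped unless ``keep_traces`` to
    keep the batch memory-light.
    """
    specs = list(specs)
    if not specs:
        return []
    gamma = specs[0].gamma
    threshold = specs[0].entropy_threshold
    max_steps = specs[0].max_steps
    for s in specs:
        if (s.gamma, s.entropy_threshold, s.max_steps) != (gamma, threshold, max_steps):
            raise ParameterError("batched trials must share gamma, "
                                 "entropy_threshold and max_steps")

    k = len(specs)
    sem_a = np.stack([sem_map.initial_state(lexicon.rgb(s.target)).activation
                      for s in specs])
    lex_rows = []
    for s in specs:
        if s.condition == "no_input":
            lex_rows.append(np.zeros(lex_map.n_units_))
        else:
            lex_rows.append(lex_map.initial_state(
                lexicon.lexical_vector(s.distractor), scale=s.r_lex).activation)
    lex_a = np.stack(lex_rows)

    w_sem, w_lex = sem_map.lateral_, lex_map.lateral_
    cell_t = lex_map.cell_matrix_.T      # (N_lex, n_colors)
    labels = lex_map.labels_
    n_colors = cell_t.shape[1]
    max_entropy = math.log2(n_colors)
    alpha_s, beta_s = sem_map.alpha, sem_map.beta
    alpha_l, beta_l = lex_map.alpha, lex_map.beta
    weights = assoc.weights_

    active = np.arange(k)
    out = [None] * k
    steps = np.full(k, max_steps, dtype=int)
    converged = np.zeros(k, dtype=bool)
    traces: list[list[float]] = [[] for _ in range(k)]

    for t in range(1, max_steps + 1):
        if active.size == 0:
            break
        sem_a = np.maximum(alpha_s * sem_a + beta_s * (sem_a @ w_sem), 0.0)
        lex_a = np.maximum(alpha_l * lex_a + beta_l * (lex_a @ w_lex), 0.0)
        lex_a += gamma * (sem_a @ weights)
        L = lex_a @ cell_t
        totals = L.sum(axis=1)
        h = np.full(active.size, max_entropy)
        pos = totals > 0
        if np.any(pos):
            p = L[pos] / totals[pos, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(p > 0, p * np.log2(p), 0.0)
            h[pos] = -plogp.sum(axis=1)
        if keep_traces:
            for row, idx in enumerate(active):
                traces[idx].append(float(h[row]))
        done = h < threshold
        if np.any(done):
            for row in np.flatnonzero(done):
                idx = active[row]
                out[idx] = labels[int(np.argmax(L[row]))]
                steps[idx] = t
                converged[idx] = True
            keep = ~done
            active = active[keep]
            sem_a = sem_a[keep]
            lex_a = lex_a[keep]

    results = []
    for i, s in enumerate(specs):
        output = out[i]
        results.append(TrialResult(
            spec=s, output=output,
            correct=bool(converged[i] and output == s.target),
            steps=int(steps[i]), converged=bool(converged[i]),
            entropy_trace=traces[i] if keep_traces else []))
    return results


def run_factorial(sem_map, lex_map, assoc, lexicon, r_lex=0.45, gamma=0.05,
                  entropy_threshold=1.0, max_steps=500) -> list[TrialResult]:
    """Run the complete factorial design: 16 congruent + 16 no-input +
    240 incongruent = 272 trials.  Deterministic given the trained model."""
    specs = _factorial_specs(lexicon, r_lex, gamma, entropy_threshold, max_steps)
    return run_trials_batch(sem_map, lex_map, assoc, lexicon, specs)


@dataclass
class ConditionSummary:
    """Accuracy and response-time statistics for one condition.

    Response-time statistics are computed over correct trials only; when a
    condition has no correct trials they are reported as NaN (undefined),
    never as zero.
    """

    condition: str
    n_trials: int
    n_correct: int
    accuracy: float          # percent
    mean_rt: float           # steps, correct trials
    se_rt: float             # steps, correct trials

    @classmethod
    def from_results(cls, condition, results) -> "ConditionSummary":
        results = list(results)
        n = len(results)
        correct_steps = np.array([r.steps for r in results if r.correct], dtype=float)
        k = correct_steps.size
        if k == 0:
            mean_rt, se_rt = math.nan, math.nan
        else:
            mean_rt = float(correct_steps.mean())
            se_rt = (float(correct_steps.std(ddof=1) / math.sqrt(k))
                     if k > 1 else math.nan)
        return cls(condition=condition, n_trials=n, n_correct=int(k),
                   accuracy=100.0 * k / n, mean_rt=mean_rt, se_rt=se_rt)


def summarize(results) -> dict:
    """Per-condition :class:`ConditionSummary` plus pooled accuracy.

    Returns a dict with one entry per condition present in ``results`` and
    an ``"overall"`` key holding the pooled percent-correct.
    """
    results = list(results)
    if not results:
        raise DataError("no trial results to summarize")
    out: dict = {}
    for cond in CONDITIONS:
        cond_results = [r for r in results if r.spec.condition == cond]
        if cond_results:
            out[cond] = ConditionSummary.from_results(cond, cond_results)
    out["overall"] = 100.0 * sum(r.correct for r in results) / len(results)
    return out


def _per_color_rts(results, condition):
    rts: dict[str, list[float]] = {}
    for r in results:
        if r.spec.condition == condition and r.correct:
            rts.setdefault(r.spec.target, []).append(float(r.steps))
    return rts


def _mean_group_diff(groups):
    # groups: list of (rts_a, rts_b); statistic = mean over groups of
    # (mean(a) - mean(b))
    return float(np.mean([np.mean(a) - np.mean(b) for a, b in groups]))


def rt_contrast_test(results, conditions=("incongruent", "no_input"),
                     baseline="congruent", n_permutations=5000, seed=0) -> dict:
    """Per-color paired response-time contrasts with permutation p-values.

    For each condition in ``conditions`` the statistic is the mean over
    target colors of (mean correct-trial RT in that condition minus mean
    correct-trial RT in the baseline).  The null distribution shuffles
    condition labels within each color group; when the number of distinct
    reassignments is at most ``n_permutations`` the test enumerates them
    exhaustively (exact p), otherwise it samples with the add-one Monte
    Carlo estimate.  Two-sided p-values.
    """
    results = list(results)
    base_rts = _per_color_rts(results, baseline)
    out: dict = {}
    for cond in conditions:
        cond_rts = _per_color_rts(results, cond)
        colors = sorted(set(base_rts) & set(cond_rts))
        if not colors:
            raise DataError(
                f"no color has correct trials in both {cond!r} and {baseline!r}")
        groups = [(cond_rts[c], base_rts[c]) for c in colors]
        observed = _mean_group_diff(groups)

        sizes = [(len(a), len(b)) for a, b in groups]
        n_exact = 1
        for ka, kb in sizes:
            n_exact *= math.comb(ka + kb, ka)
            if n_exact > n_permutations:
                break

        per_color = {c: float(np.mean(a) - np.mean(b))
                     for c, (a, b) in zip(colors, groups)}
        pools = [np.array(a + b) for a, b in groups]
        if n_exact <= n_permutations:
            count, total = 0, 0
            choices = [list(itertools.combinations(range(len(pool)), sizes[i][0]))
                       for i, pool in enumerate(pools)]
            for combo in itertools.product(*choices):
                perm_groups = []
                for pool, pick in zip(pools, combo):
                    mask = np.zeros(len(pool), dtype=bool)
                    mask[list(pick)] = True
                    perm_groups.append((pool[mask], pool[~mask]))
                stat = _mean_group_diff(perm_groups)
                total += 1
                if abs(stat) >= abs(observed) - 1e-12:
                    count += 1
            p = count / total
            exact = True
        else:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                perm_groups = []
                for pool, (ka, _) in zip(pools, sizes):
                    shuffled = rng.permutation(pool)
                    perm_groups.append((shuffled[:ka], shuffled[ka:]))
                if abs(_mean_group_diff(perm_groups)) >= abs(observed) - 1e-12:
                    count += 1
            p = (count + 1) / (n_permutations + 1)
            exact = False
        out[cond] = {"difference": observed, "p_value": p,
                     "per_color": per_color, "exact": exact,
                     "n_colors": len(colors)}
    return out


class StroopModel(BaseEstimator):
    """End-to-end Stroop model: two laterally connected maps plus routing.

    ``fit`` trains a semantic map on the lexicon's RGB vectors, a lexical
    map on its phonetic vectors, and the Hebbian associative connections
    between them.  ``run_factorial``/``run_trial`` then execute the task.
    One master seed drives independent substreams for the two maps and the
    associative training, so reruns are bit-reproducible.

    Parameters mirror the underlying estimators; the two maps share all
    settings except their softmax temperatures (semantic 0.7, lexical 0.5).
    ``r_lex`` scales the distractor's initial lexical activation and
    ``gamma`` (also called r_sem) the per-step semantic-to-lexical transfer.
    """

    def __init__(self, rows=20, cols=20, sem_temperature=0.7,
                 lex_temperature=0.5, temperature_end=0.05, alpha=0.8, beta=0.1,
                 sigma_start=2.0, sigma_end=0.25,
                 eta_start=0.2, eta_end=0.05, epochs=1000, settle_steps=30,
                 assoc_epochs=10, theta=0.1, gamma=0.05, r_lex=0.45,
                 entropy_threshold=1.0, max_steps=500, seed=0):
        self.rows = rows
        self.cols = cols
        self.sem_temperature = sem_temperature
        self.lex_temperature = lex_temperature
        self.temperature_end = temperature_end
        self.alpha = alpha
        self.beta = beta
        self.sigma_start = sigma_start
        self.sigma_end = sigma_end
        self.eta_start = eta_start
        self.eta_end = eta_end
        self.epochs = epochs
        self.settle_steps = settle_steps
        self.assoc_epochs = assoc_epochs
        self.theta = theta
        self.gamma = gamma
        self.r_lex = r_lex
        self.entropy_threshold = entropy_threshold
        self.max_steps = max_steps
        self.seed = seed

    def _som_params(self, temperature, seed):
        return dict(rows=self.rows, cols=self.cols, temperature=temperature,
                    temperature_end=min(temperature, self.temperature_end),
                    alpha=self.alpha, beta=self.beta,
                    sigma_start=self.sigma_start, sigma_end=self.sigma_end,
                    eta_start=self.eta_start, eta_end=self.eta_end,
                    epochs=self.epochs, settle_steps=self.settle_steps,
                    seed=seed)

    def fit(self, X=None, y=None):
        """Train maps and associative connections.

        ``X`` may be a :class:`~stroopsom.stimuli.ColorLexicon`; by default
        the shipped 16-color lexicon is used.
        """
        lexicon = X if isinstance(X, ColorLexicon) else default_lexicon()
        master = np.random.default_rng(self.seed)
        sem_seed, lex_seed, assoc_seed = (
            int(s) for s in master.integers(0, 2**31 - 1, size=3))
        self.lexicon_ = lexicon
        self.semantic_map_ = LateralSOM(
            **self._som_params(self.sem_temperature, sem_seed)
        ).fit(lexicon.semantic_input_set)
        self.lexical_map_ = LateralSOM(
            **self._som_params(self.lex_temperature, lex_seed)
        ).fit(lexicon.lexical_input_set)
        self.associations_ = HebbianAssociator(
            theta=self.theta, gamma=self.gamma, epochs=self.assoc_epochs,
            entropy_threshold=self.entropy_threshold,
            max_steps=self.max_steps, seed=assoc_seed,
        ).fit(self.semantic_map_, self.lexical_map_)
        return self

    def _spec(self, condition, target, distractor, r_lex, gamma):
        return TrialSpec(
            condition=condition, target=target, distractor=distractor,
            r_lex=self.r_lex if r_lex is None else r_lex,
            gamma=self.gamma if gamma is None else gamma,
            entropy_threshold=self.entropy_threshold, max_steps=self.max_steps)

    def run_trial(self, condition, target, distractor=None, r_lex=None,
                  gamma=None, record_snapshots=False) -> TrialResult:
        check_is_fitted(self, "associations_")
        if condition == "congruent" and distractor is None:
            distractor = target
        spec = self._spec(condition, target, distractor, r_lex, gamma)
        return run_trial(self.semantic_map_, self.lexical_map_,
                         self.associations_, self.lexicon_, spec,
                         record_snapshots=record_snapshots)

    def run_factorial(self, r_lex=None, gamma=None) -> list[TrialResult]:
        """All 272 factorial trials at the given (or fitted) routing
        parameters."""
        check_is_fitted(self, "associations_")
        return run_factorial(
            self.semantic_map_, self.lexical_map_, self.associations_,
            self.lexicon_,
            r_lex=self.r_lex if r_lex is None else r_lex,
            gamma=self.gamma if gamma is None else gamma,
            entropy_threshold=self.entropy_threshold, max_steps=self.max_steps)

    def predict(self, specs) -> np.ndarray:
        """Emitted color for each :class:`TrialSpec` (``None`` on failure)."""
        check_is_fitted(self, "associations_")
        return np.array(
            [run_trial(self.semantic_map_, self.lexical_map_,
                       self.associations_, self.lexicon_, s).output
             for s in specs], dtype=object)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "associations_")
        return {
            "params": self.get_params(),
            "lexicon": self.lexicon_.to_dict(),
            "semantic_map": self.semantic_map_.to_dict(),
            "lexical_map": self.lexical_map_.to_dict(),
            "assoc_weights": self.associations_.weights_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StroopModel":
        model = cls(**d["params"])
        model.lexicon_ = ColorLexicon.from_dict(d["lexicon"])
        model.semantic_map_ = LateralSOM.from_dict(d["semantic_map"])
        model.lexical_map_ = LateralSOM.from_dict(d["lexical_map"])
        assoc = HebbianAssociator(theta=model.theta, gamma=model.gamma,
                                  epochs=model.assoc_epochs,
                                  entropy_threshold=model.entropy_threshold,
                                  max_steps=model.max_steps)
        assoc.weights_ = np.asarray(d["assoc_weights"], dtype=float)
        assoc.n_semantic_units_, assoc.n_lexical_units_ = assoc.weights_.shape
        model.associations_ = assoc
        return model
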