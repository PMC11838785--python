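"""Laterally connected self-organizing map with an entropy-based readout.

The map is a 2-D grid of units, each carrying a feature vector.  Unlike a
classical Kohonen SOM, activation is not reduced to a single best-matching
unit: an input produces a graded initial activation (a softmax over unit
similarities), which then *settles* over discrete time steps through
short-range Gaussian excitation and uniform long-range inhibition.  The
settling step count is the model's analogue of response time.

The map is read out through the Voronoi partition of its units with respect
to the training inputs: the likelihood of input ``c`` is the summed
activation of the units closest to ``c``.  The Shannon entropy of this
likelihood distribution measures the map's uncertainty; the map responds
when entropy drops below a threshold (1 bit in all reported experiments).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import softmax
from scipy.stats import entropy as _scipy_entropy
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, ParameterError

__all__ = [
    "ActivationState",
    "InputSet",
    "LateralSOM",
    "build_lateral_kernels",
    "entropy_bits",
    "initial_activation",
    "likelihood_distribution",
    "max_likelihood_response",
    "settle_step",
    "train_map",
]


@dataclass
class ActivationState:
    """Per-unit activation at time ``t`` plus the entropy trace so far.

    ``t`` counts the settle steps applied since the state was created;
    ``entropy_trace`` holds the readout entropy (bits) recorded at each
    step where the caller evaluated it.
    """

    activation: np.ndarray
    t: int = 0
    entropy_trace: list[float] = field(default_factory=list)

    def copy(self) -> "ActivationState":
        return ActivationState(self.activation.copy(), self.t, list(self.entropy_trace))


class InputSet:
    """A labelled set of input feature vectors.

    Carries the median pairwise Euclidean distance ``median_pairwise_distance``
    (often written C_m), which normalizes the similarity scale in the
    initial-activation softmax so that the temperature parameter is
    comparable across feature spaces with different metric scales.
    """

    def __init__(self, vectors: np.ndarray, labels=None):
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[0] < 2:
            raise DataError("input set needs a 2-D array with at least two vectors")
        if labels is None:
            labels = list(range(vectors.shape[0]))
        labels = list(labels)
        if len(labels) != vectors.shape[0]:
            raise DataError("labels length does not match number of vectors")
        self.vectors = vectors
        self.labels = labels
        self.median_pairwise_distance = float(np.median(pdist(vectors)))

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]


def _grid_squared_distances(rows: int, cols: int) -> np.ndarray:
    """Squared Euclidean distances between all pairs of grid positions."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    return cdist(coords, coords, metric="sqeuclidean")


def build_lateral_kernels(rows: int, cols: int, sigma: float):
    """Build the excitatory and inhibitory lateral weight matrices.

    Excitatory weights follow a Gaussian of the grid distance with standard
    deviation ``sigma`` (self-connection included); inhibitory weights are
    uniform over all *other* units.  Each unit's outgoing row of each matrix
    is normalized to sum to one.

    Returns
    -------
    (W_plus, W_minus) : pair of (N, N) arrays, N = rows * cols
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ParameterError("the map needs at least two units")
    d2 = _grid_squared_distances(rows, cols)
    w_plus = np.exp(-d2 / (2.0 * sigma**2))
    w_plus /= w_plus.sum(axis=1, keepdims=True)
    n = rows * cols
    w_minus = np.ones((n, n))
    np.fill_diagonal(w_minus, 0.0)
    w_minus /= w_minus.sum(axis=1, keepdims=True)
    return w_plus, w_minus


def entropy_bits(dist: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in bits (0*log 0 = 0)."""
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise DataError("probability vector has negative entries")
    total = dist.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
        raise DataError(f"probability vector sums to {total}, expected 1")
    return float(_scipy_entropy(dist, base=2))


def max_likelihood_response(dist, labels):
    """Label of the most likely input; ``None`` when the distribution is
    undetermined (all-zero activation).  Exact ties resolve to the lowest
    label index."""
    if dist is None:
        return None
    dist = np.asarray(dist, dtype=float)
    return labels[int(np.argmax(dist))]


def _decayed(start: float, end: float, epoch: int, epochs: int) -> float:
    """Exponential interpolation from ``start`` (epoch 0) to ``end`` (last)."""
    if epochs <= 1:
        return start
    return start * (end / start) ** (epoch / (epochs - 1))


class LateralSOM(BaseEstimator):
    """Self-organizing map with lateral settling dynamics.

    Parameters
    ----------
    rows, cols : int, default 20
        Grid dimensions.
    temperature : float, default 0.7
        Softmax temperature of the initial activation; lower values focus
        the initial activation more sharply on similar units.
    temperature_end : float, default 0.05
        Floor of the training-time temperature anneal.  During training the
        softmax temperature decays exponentially from ``temperature`` to
        this value alongside the sigma and eta schedules, sharpening the
        effective learning neighborhood so that nearby inputs acquire
        separate map territories (the settling analogue of the shrinking
        winner neighborhood in a classical SOM).  All post-training
        dynamics use ``temperature`` unchanged.
    alpha : float in (0, 1], default 0.8
        Activation persistence per settle step (how slowly activation fades).
    beta : float >= 0, default 0.1
        Gain of the lateral (excitatory minus inhibitory) interaction.
    sigma_start, sigma_end : float, defaults 2.0, 0.25
        Excitatory Gaussian neighborhood width, decayed exponentially over
        training epochs.
    eta_start, eta_end : float, defaults 0.2, 0.05
        Learning rate, decayed exponentially over training epochs.
    epochs : int, default 1000
        Training epochs; each epoch presents every input once in a
        seeded-random order.
    settle_steps : int, default 30
        Settle steps applied per training presentation before the
        feature-vector update.
    seed : int, default 0
        Seed for unit initialization and presentation order; training is
        bit-reproducible for a fixed seed.

    Attributes
    ----------
    units_ : (N, d) array
        Trained unit feature vectors (N = rows * cols).
    excitatory_, inhibitory_ : (N, N) arrays
        Row-normalized lateral kernels at the final sigma.
    input_set_ : InputSet
        The training inputs, labels, and median pairwise distance.
    cells_ : (N,) int array
        Voronoi assignment of each unit to its nearest training input.
    """

    def __init__(self, rows=20, cols=20, temperature=0.7, temperature_end=0.05,
                 alpha=0.8, beta=0.1,
                 sigma_start=2.0, sigma_end=0.25, eta_start=0.2, eta_end=0.05,
                 epochs=1000, settle_steps=30, seed=0):
        self.rows = rows
        self.cols = cols
        self.temperature = temperature
        self.temperature_end = temperature_end
        self.alpha = alpha
        self.beta = beta
        self.sigma_start = sigma_start
        self.sigma_end = sigma_end
        self.eta_start = eta_start
        self.eta_end = eta_end
        self.epochs = epochs
        self.settle_steps = settle_steps
        self.seed = seed

    # -- validation -------------------------------------------------------

    def _check_params(self):
        p = self
        for name in ("rows", "cols", "epochs", "settle_steps"):
            if int(getattr(p, name)) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        for name in ("temperature", "temperature_end", "sigma_start",
                     "sigma_end", "eta_start", "eta_end"):
            if getattr(p, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if p.temperature_end > p.temperature:
            raise ParameterError("temperature_end must not exceed temperature")
        if not (0.0 < p.alpha <= 1.0):
            raise ParameterError("alpha must lie in (0, 1]")
        if p.beta < 0:
            raise ParameterError("beta must be nonnegative")
        if p.sigma_end > p.sigma_start:
            raise ParameterError("sigma_end must not exceed sigma_start")
        if p.eta_end > p.eta_start:
            raise ParameterError("eta_end must not exceed eta_start")

    # -- training ---------------------------------------------------------

    def fit(self, X, y=None):
        """Train the map on the input set ``X`` (rows are feature vectors).

        ``y`` optionally provides input labels (defaults to indices).
        """
        self._check_params()
        input_set = X if isinstance(X, InputSet) else InputSet(X, y)
        X = input_set.vectors
        n_units = self.rows * self.cols
        rng = np.random.default_rng(self.seed)

        lo, hi = X.min(axis=0), X.max(axis=0)
        units = rng.uniform(lo, hi, size=(n_units, X.shape[1]))

        cm = input_set.median_pairwise_distance
        if cm == 0:
            raise DataError("degenerate input set: median pairwise distance is zero")
        d2_grid = _grid_squared_distances(self.rows, self.cols)

        for epoch in range(self.epochs):
            eta = _decayed(self.eta_start, self.eta_end, epoch, self.epochs)
            sigma = _decayed(self.sigma_start, self.sigma_end, epoch, self.epochs)
            temp = _decayed(self.temperature, self.temperature_end,
                            epoch, self.epochs)
            w_plus = np.exp(-d2_grid / (2.0 * sigma**2))
            w_plus /= w_plus.sum(axis=1, keepdims=True)
            w = w_plus.copy()
            off = 1.0 / (n_units - 1)
            w -= off
            np.fill_diagonal(w, np.diagonal(w_plus))  # inhibition excludes self
            for idx in rng.permutation(len(input_set)):
                c = X[idx]
                a = softmax(-((units - c) ** 2).sum(axis=1) / (cm * temp))
                for _ in range(self.settle_steps):
                    a = np.maximum(self.alpha * a + self.beta * (a @ w), 0.0)
                # The settling dynamics are positively homogeneous, so the
                # absolute scale of the settled pattern is a convention;
                # pin it at unit total mass before the feature update so
                # the learning rate is meaningful across epochs.
                total = a.sum()
                if total > 0:
                    a = a / total
                units += (eta * a)[:, None] * (c - units)

        self.input_set_ = input_set
        self.labels_ = list(input_set.labels)
        self.units_ = units
        self.n_units_ = n_units
        self.n_features_in_ = X.shape[1]
        self.excitatory_, self.inhibitory_ = build_lateral_kernels(
            self.rows, self.cols, _decayed(self.sigma_start, self.sigma_end,
                                           self.epochs - 1, self.epochs))
        self.lateral_ = self.excitatory_ - self.inhibitory_
        self._assign_cells(input_set)
        return self

    def _assign_cells(self, input_set: InputSet):
        # Voronoi partition of units over inputs; argmin ties -> lowest index
        dists = cdist(self.units_, input_set.vectors)
        self.cells_ = np.argmin(dists, axis=1)
        n_inputs = len(input_set)
        m = np.zeros((n_inputs, self.n_units_))
        m[self.cells_, np.arange(self.n_units_)] = 1.0
        self.cell_matrix_ = m

    # -- dynamics ---------------------------------------------------------

    def initial_state(self, c, scale: float = 1.0) -> ActivationState:
        """Initial activation for input vector ``c``: ``scale`` times the
        softmax of the negative squared unit distances, normalized by the
        input set's median pairwise distance and the temperature."""
        check_is_fitted(self, "units_")
        c = np.asarray(c, dtype=float)
        if c.shape != (self.n_features_in_,):
            raise DataError(f"input vector must have {self.n_features_in_} entries")
        cm = self.input_set_.median_pairwise_distance
        if cm == 0:
            raise DataError("degenerate input set: median pairwise distance is zero")
        d2 = ((self.units_ - c) ** 2).sum(axis=1)
        a = scale * softmax(-d2 / (cm * self.temperature))
        return ActivationState(a, t=0)

    def settle(self, state: ActivationState, steps: int = 1) -> ActivationState:
        """Apply ``steps`` lateral settling updates in place and return the
        state.  Each step computes alpha * a + beta * a (W+ - W-), clamped
        at zero from below."""
        check_is_fitted(self, "lateral_")
        a = state.activation
        for _ in range(steps):
            a = np.maximum(self.alpha * a + self.beta * (a @ self.lateral_), 0.0)
            state.t += 1
        state.activation = a
        return state

    def likelihood(self, activation) -> np.ndarray | None:
        """Likelihood distribution over the training inputs: activation
        summed within each input's Voronoi cell, normalized to sum to one.
        Returns ``None`` (undetermined) when total activation is zero."""
        check_is_fitted(self, "cell_matrix_")
        L = self.cell_matrix_ @ np.asarray(activation, dtype=float)
        total = L.sum()
        if total <= 0:
            return None
        return L / total

    def readout_entropy(self, activation) -> float:
        """Entropy (bits) of the likelihood distribution; maximal
        (log2 of the input count) when the distribution is undetermined."""
        dist = self.likelihood(activation)
        if dist is None:
            return math.log2(len(self.input_set_))
        return entropy_bits(dist)

    def respond(self, c, scale: float = 1.0, entropy_threshold: float = 1.0,
                max_steps: int = 500):
        """Present ``c``, settle until the readout entropy falls below
        ``entropy_threshold``, and return ``(label, steps, converged)``."""
        state = self.initial_state(c, scale)
        for t in range(1, max_steps + 1):
            self.settle(state)
            h = self.readout_entropy(state.activation)
            state.entropy_trace.append(h)
            if h < entropy_threshold:
                return max_likelihood_response(
                    self.likelihood(state.activation), self.labels_), t, True
        return None, max_steps, False

    # -- sklearn surface --------------------------------------------------

    def predict(self, X):
        """Settle each row of ``X`` to response and return the labels
        (``None`` where the map fails to converge)."""
        return np.array([self.respond(c)[0] for c in np.asarray(X, dtype=float)],
                        dtype=object)

    def transform(self, X):
        """Settled activation patterns, one row per input vector, after
        ``settle_steps`` settling steps."""
        check_is_fitted(self, "units_")
        out = np.empty((len(X), self.n_units_))
        for i, c in enumerate(np.asarray(X, dtype=float)):
            state = self.settle(self.initial_state(c), self.settle_steps)
            out[i] = state.activation
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "units_")
        return {
            "params": self.get_params(),
            "labels": self.labels_,
            "input_vectors": self.input_set_.vectors.tolist(),
            "units": self.units_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LateralSOM":
        som = cls(**d["params"])
        som._check_params()
        input_set = InputSet(np.asarray(d["input_vectors"]), d["labels"])
        som.input_set_ = input_set
        som.labels_ = list(input_set.labels)
        som.units_ = np.asarray(d["units"], dtype=float)
        som.n_units_ = som.rows * som.cols
        som.n_features_in_ = som.units_.shape[1]
        som.excitatory_, som.inhibitory_ = build_lateral_kernels(
            som.rows, som.cols, _decayed(som.sigma_start, som.sigma_end,
                                         som.epochs - 1, som.epochs))
        som.lateral_ = som.excitatory_ - som.inhibitory_
        som._assign_cells(input_set)
        return som

    def to_json(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "LateralSOM":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# -- functional wrappers ---------------------------------------------------

def initial_activation(som: LateralSOM, c, scale: float = 1.0) -> ActivationState:
    """Functional form of :meth:`LateralSOM.initial_state`."""
    return som.initial_state(c, scale)


def settle_step(som: LateralSOM, state: ActivationState) -> ActivationState:
    """One lateral settling update (functional form of ``settle(state, 1)``)."""
    return som.settle(state, 1)


def likelihood_distribution(som: LateralSOM, state: ActivationState,
                            input_set: InputSet | None = None):
    """Likelihood over inputs from the current activation.  With an explicit
    ``input_set`` the Voronoi partition is recomputed for that set."""
    if input_set is None:
        return som.likelihood(state.activation)
    dists = cdist(som.units_, input_set.vectors)
    cells = np.argmin(dists, axis=1)
    L = np.zeros(len(input_set))
    np.add.at(L, cells, state.activation)
    total = L.sum()
    if total <= 0:
        return None
    return L / total


def train_map(input_set, labels=None, **params) -> LateralSOM:
    """Train and return a :class:`LateralSOM` on the given input set."""
    return LateralSOM(**params).fit(input_set, labels)
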