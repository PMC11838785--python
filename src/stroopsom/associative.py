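"""Hebbian associative connections from the semantic map to the lexical map.

Both maps are presented with the same color; each settles until its readout
entropy falls below one bit, and connections between units that responded
to the same input are strengthened in proportion to their co-activation
(w_ij += theta * a_i * a_j).  "Responded" is taken at the level of the
map's output: the update uses the activation restricted to each map's
maximum-likelihood (winning) Voronoi cell, so units outside the responding
cell - residual activation that the 1-bit criterion still tolerates - do
not enter the association.  After each epoch every semantic unit's
outgoing weight row is normalized to sum to one.  During the Stroop task
the matrix routes semantic activation into the lexical map:
a_j += gamma * sum_i a_i w_ij.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ConvergenceError, DataError
from .lateral_som import ActivationState, LateralSOM

__all__ = [
    "HebbianAssociator",
    "hebbian_update",
    "normalize_rows",
    "train_associative",
    "transfer_activation",
]


def hebbian_update(weights: np.ndarray, sem_act: np.ndarray,
                   lex_act: np.ndarray, theta: float) -> np.ndarray:
    """In-place Hebbian increment: w_ij += theta * a_i * a_j.

    No normalization happens here; call :func:`normalize_rows` per epoch.
    """
    sem_act = np.asarray(sem_act, dtype=float)
    lex_act = np.asarray(lex_act, dtype=float)
    if weights.shape != (sem_act.size, lex_act.size):
        raise DataError(
            f"weights {weights.shape} do not match activations "
            f"({sem_act.size}, {lex_act.size})")
    weights += theta * np.outer(sem_act, lex_act)
    return weights


def normalize_rows(weights: np.ndarray) -> np.ndarray:
    """Divide each row by its sum so outgoing weights sum to one."""
    sums = weights.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise DataError(
            f"semantic unit {int(zero[0])} has no outgoing associative "
            "weight (untrained unit)")
    weights /= sums[:, None]
    return weights


class HebbianAssociator(BaseEstimator):
    """Learns and applies semantic-to-lexical associative routing.

    Parameters
    ----------
    theta : float, default 0.1
        Hebbian learning rate.
    gamma : float, default 0.05
        Transfer gain: how strongly settled semantic activation is pushed
        into the lexical map each time step (the semantic routing strength,
        also called r_sem).
    epochs : int, default 10
        Training epochs; each presents every color once in seeded-random
        order, with row normalization after each epoch.
    entropy_threshold : float, default 1.0
        Each map settles until its readout entropy is below this many bits
        before the Hebbian update is applied.
    max_steps : int, default 500
        Settling cap during training; exceeding it raises
        :class:`~stroopsom.errors.ConvergenceError`.
    seed : int, default 0

    Attributes
    ----------
    weights_ : (N_sem, N_lex) array
        Nonnegative routing weights; every row sums to one.
    """

    def __init__(self, theta=0.1, gamma=0.05, epochs=10,
                 entropy_threshold=1.0, max_steps=500, seed=0):
        self.theta = theta
        self.gamma = gamma
        self.epochs = epochs
        self.entropy_threshold = entropy_threshold
        self.max_steps = max_steps
        self.seed = seed

    @staticmethod
    def _settle_to_criterion(som: LateralSOM, c, threshold, max_steps, label):
        """Settle until the readout entropy is below ``threshold`` and return
        the activation restricted to the responding (maximum-likelihood)
        Voronoi cell, normalized to unit mass."""
        state = som.initial_state(c, 1.0)
        for _ in range(max_steps):
            som.settle(state)
            if som.readout_entropy(state.activation) < threshold:
                dist = som.likelihood(state.activation)
                winner = int(np.argmax(dist))
                a = state.activation * (som.cells_ == winner)
                return a / a.sum()
        raise ConvergenceError(
            f"map failed to reach entropy < {threshold} bits within "
            f"{max_steps} steps for color {label!r}")

    def fit(self, sem_map: LateralSOM, lex_map: LateralSOM):
        """Train routing weights between two fitted maps.

        Both maps must have been trained on input sets with identical label
        order (the same colors).
        """
        if list(sem_map.labels_) != list(lex_map.labels_):
            raise DataError("semantic and lexical maps carry different labels")
        n = len(sem_map.input_set_)
        rng = np.random.default_rng(self.seed)
        # Uniform positive initialization: no color preference before
        # training, and row normalization is well defined even for
        # semantic units that are never co-activated with anything.  The
        # magnitude is negligible against the Hebbian increments so the
        # trained, row-normalized weights reflect co-activation structure
        # rather than the initialization.
        weights = np.full((sem_map.n_units_, lex_map.n_units_),
                          1e-8 / lex_map.n_units_)
        for _ in range(self.epochs):
            for idx in rng.permutation(n):
                label = sem_map.labels_[idx]
                # Unit mass per pattern: the settled magnitude depends on
                # how many steps the entropy criterion took (the
                # homogeneous dynamics decay geometrically), so without the
                # normalization fast-settling colors would dominate.
                sem_a = self._settle_to_criterion(
                    sem_map, sem_map.input_set_.vectors[idx],
                    self.entropy_threshold, self.max_steps, label)
                lex_a = self._settle_to_criterion(
                    lex_map, lex_map.input_set_.vectors[idx],
                    self.entropy_threshold, self.max_steps, label)
                hebbian_update(weights, sem_a, lex_a, self.theta)
            normalize_rows(weights)
        self.weights_ = weights
        self.n_semantic_units_ = sem_map.n_units_
        self.n_lexical_units_ = lex_map.n_units_
        return self

    def transfer(self, sem_state: ActivationState, lex_state: ActivationState,
                 gamma: float | None = None) -> ActivationState:
        """Route settled semantic activation into the lexical map in place:
        lexical a_j += gamma * sum_i sem_a_i * w_ij.  The semantic state is
        left untouched."""
        check_is_fitted(self, "weights_")
        g = self.gamma if gamma is None else gamma
        sem_act = sem_state.activation
        if sem_act.size != self.weights_.shape[0]:
            raise DataError("semantic activation does not match weight rows")
        if lex_state.activation.size != self.weights_.shape[1]:
            raise DataError("lexical activation does not match weight columns")
        lex_state.activation = lex_state.activation + g * (sem_act @ self.weights_)
        return lex_state


def train_associative(sem_map, lex_map, epochs=10, theta=0.1, gamma=0.05,
                      entropy_threshold=1.0, max_steps=500,
                      seed=0) -> HebbianAssociator:
    """Train and return a :class:`HebbianAssociator` between two fitted maps."""
    return HebbianAssociator(theta=theta, gamma=gamma, epochs=epochs,
                             entropy_threshold=entropy_threshold,
                             max_steps=max_steps, seed=seed).fit(sem_map, lex_map)


def transfer_activation(assoc: HebbianAssociator, sem_state: ActivationState,
                        lex_state: ActivationState,
                        gamma: float | None = None) -> ActivationState:
    """Functional form of :meth:`HebbianAssociator.transfer`."""
    return assoc.transfer(sem_state, lex_state, gamma)
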