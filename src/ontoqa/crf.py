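"""Linear-chain conditional random field.

The model assigns a label sequence s = <s_1..s_n> to an observation
sequence o = <o_1..o_n> with conditional probability

    P(s|o) = (1/Z_o) exp( sum_i sum_j lambda_j f_j(s_{i-1}, s_i, o, i) )

where the f_j are binary indicator features and Z_o normalizes over all
label sequences.  Features factor into *emission* indicators (an
observation feature active at position i, paired with the state s_i),
*transition* indicators (the state pair s_{i-1}, s_i) and an initial-state
indicator.  Weights are fit by maximizing the L2-penalized conditional
log-likelihood with L-BFGS; inference is Viterbi decoding.

All computations run in log space (scipy ``logsumexp``); training with a
fixed corpus is deterministic (weights start at zero, so the seed only
matters to callers that subsample data).
"""

from __future__ import annotations

import json

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


class TrainingError(ValueError):
    """Degenerate corpus: empty, or fewer than two distinct labels."""


class LinearChainCRF:
    """First-order linear-chain CRF over string-named binary features.

    Parameters
    ----------
    l2:
        L2 regularization strength (lambda/2 * ||w||^2 added to the NLL).
    max_iter:
        L-BFGS iteration cap.
    """

    def __init__(self, l2: float = 1.0, max_iter: int = 200):
        self.l2 = float(l2)
        self.max_iter = int(max_iter)
        self.labels: list[str] = []
        self.feature_index: dict[str, int] = {}
        self.W: np.ndarray | None = None  # (n_features, n_states) emission
        self.T: np.ndarray | None = None  # (n_states, n_states) transition
        self.I: np.ndarray | None = None  # (n_states,) initial

    # -- encoding ---------------------------------------------------------

    def _encode(self, x: list[list[str]]) -> list[np.ndarray]:
        idx = self.feature_index
        return [
            np.array(sorted({idx[f] for f in feats if f in idx}), dtype=np.intp)
            for feats in x
        ]

    def _emissions(self, enc: list[np.ndarray]) -> np.ndarray:
        """Per-position state scores, shape (n, n_states)."""
        E = np.zeros((len(enc), len(self.labels)))
        for i, ids in enumerate(enc):
            if ids.size:
                E[i] = self.W[ids].sum(axis=0)
        return E

    # -- inference --------------------------------------------------------

    def _forward(self, E: np.ndarray) -> np.ndarray:
        n, S = E.shape
        alpha = np.empty((n, S))
        alpha[0] = self.I + E[0]
        for i in range(1, n):
            alpha[i] = E[i] + logsumexp(alpha[i - 1][:, None] + self.T, axis=0)
        return alpha

    def _backward(self, E: np.ndarray) -> np.ndarray:
        n, S = E.shape
        beta = np.zeros((n, S))
        for i in range(n - 2, -1, -1):
            beta[i] = logsumexp(self.T + (E[i + 1] + beta[i + 1])[None, :], axis=1)
        return beta

    def log_partition(self, x: list[list[str]]) -> float:
        """log Z_o for an observation sequence."""
        E = self._emissions(self._encode(x))
        return float(logsumexp(self._forward(E)[-1]))

    def sequence_score(self, x: list[list[str]], y: list[str]) -> float:
        """Unnormalized log score of a label sequence."""
        enc = self._encode(x)
        E = self._emissions(enc)
        states = [self.labels.index(l) for l in y]
        score = self.I[states[0]] + E[0, states[0]]
        for i in range(1, len(states)):
            score += self.T[states[i - 1], states[i]] + E[i, states[i]]
        return float(score)

    def sequence_log_prob(self, x: list[list[str]], y: list[str]) -> float:
        return self.sequence_score(x, y) - self.log_partition(x)

    def predict(self, x: list[list[str]]) -> list[str]:
        """Viterbi-decode the most probable label sequence."""
        if not x:
            return []
        E = self._emissions(self._encode(x))
        n, S = E.shape
        delta = self.I + E[0]
        back = np.zeros((n, S), dtype=np.intp)
        for i in range(1, n):
            scores = delta[:, None] + self.T
            back[i] = scores.argmax(axis=0)
            delta = E[i] + scores.max(axis=0)
        states = [int(delta.argmax())]
        for i in range(n - 1, 0, -1):
            states.append(int(back[i, states[-1]]))
        return [self.labels[s] for s in reversed(states)]

    # -- training ---------------------------------------------------------

    def fit(self, X: list, Y: list, seed: int = 0) -> "LinearChainCRF":
        """Fit weights on sequences ``X`` (per-token feature lists) with
        gold labels ``Y`` by L-BFGS on the penalized conditional NLL.

        Raises :class:`TrainingError` on an empty corpus, empty sequences
        only, or a single distinct label.
        """
        del seed  # training is deterministic; kept for interface stability
        pairs = [(x, y) for x, y in zip(X, Y) if len(x) > 0]
        if not pairs:
            raise TrainingError("training corpus is empty")
        labels = sorted({l for _, y in pairs for l in y})
        if len(labels) < 2:
            raise TrainingError("training corpus must contain at least two distinct labels")
        self.labels = labels
        feats = sorted({f for x, _ in pairs for tok in x for f in tok})
        self.feature_index = {f: i for i, f in enumerate(feats)}
        F, S = len(feats), len(labels)

        encoded = [(self._encode(x), [labels.index(l) for l in y]) for x, y in pairs]

        # empirical feature counts
        emp_W = np.zeros((F, S))
        emp_T = np.zeros((S, S))
        emp_I = np.zeros(S)
        for enc, states in encoded:
            emp_I[states[0]] += 1
            for i, ids in enumerate(enc):
                emp_W[ids, states[i]] += 1
            for a, b in zip(states, states[1:]):
                emp_T[a, b] += 1

        def unpack(theta):
            self.W = theta[: F * S].reshape(F, S)
            self.T = theta[F * S : F * S + S * S].reshape(S, S)
            self.I = theta[F * S + S * S :]

        def objective(theta):
            unpack(theta)
            nll = 0.0
            gW = np.zeros((F, S))
            gT = np.zeros((S, S))
            gI = np.zeros(S)
            for enc, states in encoded:
                E = self._emissions(enc)
                alpha = self._forward(E)
                beta = self._backward(E)
                logZ = logsumexp(alpha[-1])
                # gold score
                score = self.I[states[0]] + E[0, states[0]]
                for i in range(1, len(states)):
                    score += self.T[states[i - 1], states[i]] + E[i, states[i]]
                nll += logZ - score
                # expected counts
                post = np.exp(alpha + beta - logZ)  # (n, S) marginals
                gI += post[0]
                for i, ids in enumerate(enc):
                    gW[ids] += post[i]
                for i in range(1, len(enc)):
                    pair = np.exp(
                        alpha[i - 1][:, None] + self.T + (E[i] + beta[i])[None, :] - logZ
                    )
                    gT += pair
            grad = np.concatenate([
                (gW - emp_W).ravel(),
                (gT - emp_T).ravel(),
                (gI - emp_I),
            ])
            nll += 0.5 * self.l2 * float(theta @ theta)
            grad += self.l2 * theta
            return nll, grad

        theta0 = np.zeros(F * S + S * S + S)
        res = minimize(
            objective, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        unpack(res.x)
        return self

    # -- persistence ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "version": 1,
            "l2": self.l2,
            "labels": self.labels,
            "features": list(self.feature_index),
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "I": self.I.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "LinearChainCRF":
        obj = json.loads(text)
        model = cls(l2=obj["l2"])
        model.labels = obj["labels"]
        model.feature_index = {f: i for i, f in enumerate(obj["features"])}
        model.W = np.array(obj["W"])
        model.T = np.array(obj["T"])
        model.I = np.array(obj["I"])
        return model
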