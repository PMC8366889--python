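"""Species assignment from the six traits by linear discriminant analysis.

Classic Gaussian LDA: per-class mean vectors, one pooled within-class
covariance, class priors (proportional to class frequencies by default).
A crown is assigned to the class maximising the log posterior

    log pi_k - 0.5 (x - mu_k)' Sigma^{-1} (x - mu_k)

A small ridge (eps * trace/p on the diagonal) is added when the pooled
covariance is ill-conditioned.  Accuracy is reported for resubstitution and
leave-one-out cross-validation; both modes are recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import TRAITS

CONDITION_LIMIT = 1e8
RIDGE_EPS = 1e-6


def _pooled_fit(X: np.ndarray, y: np.ndarray, classes, priors):
    means = np.vstack([X[y == k].mean(axis=0) for k in classes])
    n, p = X.shape
    cov = np.zeros((p, p))
    for i, k in enumerate(classes):
        d = X[y == k] - means[i]
        cov += d.T @ d
    cov /= (n - len(classes))
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        cov = cov + np.eye(p) * RIDGE_EPS * np.trace(cov) / p
    return means, cov


@dataclass
class TraitDiscriminant:
    """LDA model over complete-case crowns.

    Parameters
    ----------
    trait_table : per-crown traits (rows indexed by crown_id).
    labels : Series of species labels aligned with the table index.
    priors : "proportional" (class frequencies) or "uniform".
    traits : trait columns used as features (the six by default).
    """

    trait_table: pd.DataFrame
    labels: pd.Series
    priors: str = "proportional"
    traits: tuple = TRAITS

    def fit(self) -> "DiscriminantResults":
        X_df = self.trait_table[list(self.traits)]
        keep = X_df.notna().all(axis=1) & self.labels.reindex(X_df.index).notna()
        X = X_df.loc[keep].to_numpy(dtype=float)
        y = self.labels.reindex(X_df.index).loc[keep].to_numpy()
        classes = []
        for k in pd.unique(y):
            if (y == k).sum() >= 2:
                classes.append(k)
            else:
                warnings.warn(f"class {k!r} dropped: fewer than 2 complete "
                              "cases")
        if len(classes) < 2:
            raise ValueError("need at least two classes with >= 2 cases")
        mask = np.isin(y, classes)
        X, y = X[mask], y[mask]
        classes = sorted(classes)
        counts = np.array([(y == k).sum() for k in classes], dtype=float)
        if self.priors == "proportional":
            pri = counts / counts.sum()
        elif self.priors == "uniform":
            pri = np.ones(len(classes)) / len(classes)
        else:
            raise ValueError(f"unknown priors {self.priors!r}")
        means, cov = _pooled_fit(X, y, classes, pri)
        return DiscriminantResults(
            classes=classes, means=means, pooled_cov=cov, priors=pri,
            X=X, y=y, index=X_df.index[keep][mask],
            trait_names=tuple(self.traits), priors_mode=self.priors)


@dataclass
class DiscriminantResults:
    classes: list
    means: np.ndarray
    pooled_cov: np.ndarray
    priors: np.ndarray
    X: np.ndarray
    y: np.ndarray
    index: pd.Index
    trait_names: tuple
    priors_mode: str
    _cov_inv: np.ndarray | None = field(default=None, repr=False)

    def _inv(self):
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.pooled_cov)
        return self._cov_inv

    def log_posterior(self, X: np.ndarray) -> np.ndarray:
        """Unnormalised log posterior, shape (n, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        inv = self._inv()
        out = np.empty((X.shape[0], len(self.classes)))
        for i, _ in enumerate(self.classes):
            d = X - self.means[i]
            out[:, i] = (np.log(self.priors[i])
                         - 0.5 * np.einsum("ij,jk,ik->i", d, inv, d))
        return out

    def predict(self, trait_table: pd.DataFrame):
        """Assign each complete-case crown to its arg-max posterior class."""
        X_df = trait_table[list(self.trait_names)]
        keep = X_df.notna().all(axis=1)
        lp = self.log_posterior(X_df.loc[keep].to_numpy(dtype=float))
        labels = np.array(self.classes)[lp.argmax(axis=1)]
        out = pd.Series(pd.NA, index=X_df.index, dtype=object,
                        name="predicted")
        out.loc[keep] = labels
        return out

    def accuracy(self, mode: str = "resubstitution") -> float:
        """Fraction correctly assigned among scored crowns."""
        if mode == "resubstitution":
            lp = self.log_posterior(self.X)
            pred = np.array(self.classes)[lp.argmax(axis=1)]
        elif mode == "loo":
            pred = self._loo_predictions()
        else:
            raise ValueError(f"unknown accuracy mode {mode!r}")
        return float((pred == self.y).mean())

    def _loo_predictions(self) -> np.ndarray:
        pred = np.empty(self.y.shape, dtype=object)
        for i in range(len(self.y)):
            mask = np.ones(len(self.y), dtype=bool)
            mask[i] = False
            X, y = self.X[mask], self.y[mask]
            classes = [k for k in self.classes if (y == k).sum() >= 2]
            counts = np.array([(y == k).sum() for k in classes], dtype=float)
            pri = (counts / counts.sum() if self.priors_mode == "proportional"
                   else np.ones(len(classes)) / len(classes))
            means, cov = _pooled_fit(X, y, classes, pri)
            inv = np.linalg.inv(cov)
            d = self.X[i] - means
            lp = np.log(pri) - 0.5 * np.einsum("ij,jk,ik->i", d, inv, d)
            pred[i] = classes[int(lp.argmax())]
        return pred

    def confusion_matrix(self) -> pd.DataFrame:
        pred = np.array(self.classes)[
            self.log_posterior(self.X).argmax(axis=1)]
        cm = pd.crosstab(pd.Series(self.y, name="true"),
                         pd.Series(pred, name="predicted"))
        return cm.reindex(index=self.classes, columns=self.classes,
                          fill_value=0)

    def summary(self) -> str:
        lines = [f"Linear discriminant: {len(self.classes)} classes, "
                 f"{len(self.y)} crowns, priors={self.priors_mode}",
                 f"resubstitution accuracy: {self.accuracy():.3f}",
                 f"leave-one-out accuracy:  {self.accuracy('loo'):.3f}",
                 "", "confusion (resubstitution):",
                 self.confusion_matrix().to_string()]
        return "\n".join(lines)
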