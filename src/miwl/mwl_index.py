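"""Stepwise-LDA mental-workload index.

A stepwise linear discriminant in its classical regression form: 0/1 class
labels (Easy = 0, Hard = 1) are regressed on spectral features drawn from
the 99 eligible ROI-PSD columns, with forward entry (partial-F p <= p_enter),
backward removal (p >= p_remove) and a BIC guard as the automatic stopping
rule.  The trained weights and bias score unseen epochs as

    y(t) = sum_i w_i * f_i(t) + b

and the workload index MWL_SCORE is an 8 s trailing moving average of y,
i.e. 64 epochs on the 0.125 s epoch grid.  Scores tend toward 0 in easy and
1 in hard conditions but are not clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class MWLIndexModel:
    """Selected ROI columns, their least-squares weights, and the bias."""

    selected: np.ndarray       # indices into the full ROI column space
    weights: np.ndarray
    bias: float
    n_columns: int             # width of the ROI matrix the model applies to
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.selected.size < 1:
            raise ValueError("model must select at least one feature")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selected": self.selected.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "n_columns": self.n_columns,
            "training_meta": self.training_meta,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MWLIndexModel":
        d = json.loads(Path(path).read_text())
        return cls(
            selected=np.array(d["selected"]), weights=np.array(d["weights"]),
            bias=d["bias"], n_columns=d["n_columns"],
            training_meta=d.get("training_meta", {}),
        )


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coef incl. intercept last, RSS)."""
    A = np.column_stack([X, np.ones(len(y))])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def _partial_f_p(rss_small: float, rss_big: float, n: int, k_big: int) -> float:
    """p-value of the partial F test for one added regressor.

    ``k_big`` counts regressors including the intercept in the larger model.
    """
    dof = n - k_big
    if dof <= 0 or rss_big <= 0:
        return 0.0
    f = (rss_small - rss_big) / (rss_big / dof)
    return float(stats.f.sf(max(f, 0.0), 1, dof))


def train_asswlda(
    roi_train: np.ndarray, labels: np.ndarray, eligible: np.ndarray,
    p_enter: float = 0.05, p_remove: float = 0.10,
    bic_guard: bool = True, max_features: int | None = None,
) -> MWLIndexModel:
    """Forward-backward stepwise selection with an automatic stop.

    At each forward step the eligible candidate giving the lowest residual
    sum of squares is admitted if its partial-F p-value is at most
    ``p_enter`` and (with the BIC guard on) the BIC improves; included
    features whose removal p-value reaches ``p_remove`` are dropped.  The
    procedure stops when no candidate qualifies.  Final weights and bias are
    the least-squares fit of the 0/1 labels on the selected columns.
    """
    X = np.asarray(roi_train, dtype=float)
    y = np.asarray(labels, dtype=float)
    eligible = np.asarray(eligible, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("roi_train and labels are misaligned")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in the training labels")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("labels must be coded 0/1")
    candidates = np.flatnonzero(eligible)
    if candidates.size == 0:
        raise ValueError("no eligible features")
    n = y.size
    if max_features is None:
        max_features = candidates.size

    selected: list[int] = []
    _, rss_cur = _ols_rss(np.empty((n, 0)), y)
    bic_cur = n * np.log(rss_cur / n) + 1 * np.log(n)
    trace = []
    while len(selected) < max_features:
        remaining = [j for j in candidates if j not in selected]
        if not remaining:
            break
        best_j, best_rss = None, np.inf
        for j in remaining:
            _, rss_j = _ols_rss(X[:, selected + [j]], y)
            if rss_j < best_rss:
                best_j, best_rss = j, rss_j
        k_big = len(selected) + 2  # new feature + intercept
        p_add = _partial_f_p(rss_cur, best_rss, n, k_big)
        if p_add > p_enter:
            break
        if bic_guard:
            bic_new = n * np.log(max(best_rss, 1e-300) / n) + k_big * np.log(n)
            if bic_new >= bic_cur:
                trace.append({"action": "stop_bic", "candidate": int(best_j)})
                break
            bic_cur = bic_new
        selected.append(int(best_j))
        rss_cur = best_rss
        trace.append({"action": "add", "feature": int(best_j), "p": p_add})

        # backward sweep
        changed = True
        while changed and len(selected) > 1:
            changed = False
            worst_i, worst_p = None, -1.0
            for i in selected:
                others = [s for s in selected if s != i]
                _, rss_wo = _ols_rss(X[:, others], y)
                p_rm = _partial_f_p(rss_wo, rss_cur, n, len(selected) + 1)
                if p_rm > worst_p:
                    worst_i, worst_p = i, p_rm
            if worst_p >= p_remove:
                selected.remove(worst_i)
                _, rss_cur = _ols_rss(X[:, selected], y)
                bic_cur = n * np.log(rss_cur / n) + (len(selected) + 1) * np.log(n)
                trace.append({"action": "remove", "feature": int(worst_i), "p": worst_p})
                changed = True

    if not selected:
        # stepwise admitted nothing: fall back to the single best candidate so
        # the model is always scorable; recorded in the stopping trace
        best_j = min(candidates, key=lambda j: _ols_rss(X[:, [j]], y)[1])
        selected = [int(best_j)]
        trace.append({"action": "fallback_single", "feature": int(best_j)})

    coef, rss = _ols_rss(X[:, selected], y)
    return MWLIndexModel(
        selected=np.array(selected), weights=coef[:-1], bias=float(coef[-1]),
        n_columns=X.shape[1],
        training_meta={
            "p_enter": p_enter, "p_remove": p_remove, "bic_guard": bic_guard,
            "n_train": int(n), "rss": rss, "steps": trace,
        },
    )


def apply_discriminant(model: MWLIndexModel, roi_test: np.ndarray) -> np.ndarray:
    """y(t) = sum_i w_i * f_i(t) + b for every epoch row; no clipping."""
    X = np.asarray(roi_test, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_columns:
        raise ValueError(
            f"expected {model.n_columns} feature columns, got {X.shape[1] if X.ndim == 2 else 'non-matrix'}"
        )
    return X[:, model.selected] @ model.weights + model.bias


def smooth_mwl_score(
    y: np.ndarray, shift_s: float = 0.125, window_s: float = 8.0
) -> np.ndarray:
    """Trailing moving average of the discriminant over an 8 s window.

    The window spans round(window_s / shift_s) epochs (64 by default); the
    first window-1 values average over the available prefix (expanding
    warm-up), so output and input have equal length.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty score series")
    w = int(round(window_s / shift_s))
    cs = np.concatenate(([0.0], np.cumsum(y)))
    out = np.empty_like(y)
    n = y.size
    head = min(w, n)
    out[:head] = cs[1:head + 1] / np.arange(1, head + 1)
    if n > w:
        out[w:] = (cs[w + 1:] - cs[1:n - w + 1]) / w
    return out
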