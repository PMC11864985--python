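"""One-hidden-layer Cox partial-likelihood network (DeepSurv-style).

The model maps the feature-expanded marker vector of a patient to a scalar
proportional-hazards risk score through a single fully connected hidden layer
of width 10x the input, with a rectifier nonlinearity, trained by minimizing
the negative Cox partial log-likelihood (Breslow tie handling, computed per
mini-batch) with Adam.  The training schedule runs staged learning rates
1e-2 -> 1e-3 -> 1e-4, each stage up to 50 epochs with early stopping on the
validation partial likelihood; dropout (rate 0.5) is applied to the inputs and
the hidden layer during training only.  The input dropout decorrelates input
variables, which sharpens the per-input relevance attribution downstream.

Exposes a statsmodels-style model object: ``CoxRiskNet(data).fit()`` returns a
:class:`CoxRiskNetResults` carrying the trained weights, training history,
predictions, explanations and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import CohortTable, SurvivalOutcome
from .preprocess import ExpandedMatrix, Preprocessor

__all__ = [
    "CoxNet",
    "TrainConfig",
    "CoxRiskNet",
    "CoxRiskNetResults",
    "CVResult",
    "build_network",
    "train",
    "cross_validate",
    "concordance",
    "cox_partial_loss_grad",
]


# ---------------------------------------------------------------------------
# loss


def cox_partial_loss_grad(scores, time, event):
    """Negative Cox partial log-likelihood (Breslow ties) and its gradient.

    Both are normalized by the number of events so the learning rate is
    insensitive to batch size.  Requires at least one event.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    n_events = e.sum()
    if n_events < 1:
        raise ValueError("Cox partial likelihood needs at least one event")
    order = np.argsort(t, kind="stable")
    s_o, e_o, t_o = s[order], e[order], t[order]
    m = s_o.max()
    es = np.exp(s_o - m)
    rev_cum = np.cumsum(es[::-1])[::-1]
    first = np.ones(len(t_o), dtype=bool)
    first[1:] = t_o[1:] != t_o[:-1]
    gidx = np.cumsum(first) - 1
    group_risk = rev_cum[first]               # shifted risk-set sums, one per unique time
    events_per_group = np.bincount(gidx, weights=e_o)
    cum = np.cumsum(events_per_group / group_risk)[gidx]
    loglik = float(np.sum(e_o * (s_o - m - np.log(group_risk[gidx]))))
    grad_o = -(e_o - es * cum) / n_events
    grad = np.empty_like(grad_o)
    grad[order] = grad_o
    return -loglik / n_events, grad


# ---------------------------------------------------------------------------
# network


def _relu(z):
    return np.maximum(z, 0.0)


@dataclass
class CoxNet:
    """Weights of the one-hidden-layer risk network (rectifier activation)."""

    W1: np.ndarray  # (input, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    activation: str = "relu"

    @property
    def input_width(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_width(self) -> int:
        return self.W1.shape[1]

    def forward(self, X: np.ndarray):
        """Deterministic forward pass; returns (risk, hidden pre-activations, activations)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"input width {X.shape[1]} does not match network input {self.input_width}"
            )
        Z1 = X @ self.W1 + self.b1
        A1 = _relu(Z1)
        out = A1 @ self.W2 + self.b2
        return out, Z1, A1

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        """Per-patient risk score; dropout disabled."""
        return self.forward(X)[0]

    def copy_weights(self):
        return (self.W1.copy(), self.b1.copy(), self.W2.copy(), float(self.b2))

    def set_weights(self, w):
        self.W1, self.b1, self.W2, self.b2 = w[0].copy(), w[1].copy(), w[2].copy(), float(w[3])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "input_width": self.input_width,
            "hidden_width": self.hidden_width,
            "activation": self.activation,
            "W1": self.W1.ravel().tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxNet":
        d = json.loads(Path(path).read_text())
        W1 = np.array(d["W1"], dtype=float).reshape(d["input_width"], d["hidden_width"])
        return cls(W1, np.array(d["b1"], dtype=float), np.array(d["W2"], dtype=float),
                   float(d["b2"]), d.get("activation", "relu"))


def build_network(input_width: int, seed: int = 0, hidden_multiplier: int = 10) -> CoxNet:
    """Network with hidden width = 10 x input width, Kaiming-uniform initialized.

    Weights and biases are drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in)), the
    default of the torch Linear layers used by the DeepSurv family of models;
    the small scale keeps the first high-learning-rate training stage stable.
    """
    if input_width < 1:
        raise ValueError("input_width must be >= 1")
    hidden = hidden_multiplier * input_width
    rng = np.random.default_rng(seed)
    k1 = 1.0 / np.sqrt(input_width)
    k2 = 1.0 / np.sqrt(hidden)
    return CoxNet(
        W1=rng.uniform(-k1, k1, size=(input_width, hidden)),
        b1=rng.uniform(-k1, k1, size=hidden),
        W2=rng.uniform(-k2, k2, size=hidden),
        b2=float(rng.uniform(-k2, k2)),
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    lr0: float = 0.01
    lr_min: float = 1e-4
    lr_decay: float = 10.0
    epochs_per_stage: int = 50
    dropout: float = 0.5
    input_dropout: float = 0.5
    batch_size: int = 1024
    patience: int = 10
    val_fraction: float = 0.1
    hidden_multiplier: int = 10
    seed: int = 0

    def stages(self) -> list[float]:
        out, lr = [], self.lr0
        while lr >= self.lr_min * (1 - 1e-12):
            out.append(lr)
            lr /= self.lr_decay
        return out


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _val_loss(net: CoxNet, X, time, event) -> float:
    risk = net.predict_risk(X)
    return cox_partial_loss_grad(risk, time, event)[0]


def train(
    net: CoxNet,
    X: np.ndarray,
    outcome: SurvivalOutcome,
    config: TrainConfig | None = None,
    val: tuple[np.ndarray, SurvivalOutcome] | None = None,
    input_groups: np.ndarray | None = None,
):
    """Staged Adam training with early stopping on validation partial likelihood.

    If no validation set is supplied, ``config.val_fraction`` of the rows is
    split off (event-stratified).  ``input_groups`` maps each input column to
    a variable index: input dropout then masks whole variables, so the two
    slots of a feature-expanded marker are always dropped together (a
    half-dropped pair would collide with the (0,0) missingness code).
    Returns the network holding the weights of the best validation epoch,
    plus a history dict.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(config.seed)
    if input_groups is None:
        input_groups = np.arange(X.shape[1])
    else:
        input_groups = np.asarray(input_groups)
    n_groups = int(input_groups.max()) + 1

    if val is None:
        split_seed = int(rng.integers(2**31 - 1))
        try:
            idx_tr, idx_val = train_test_split(
                np.arange(len(X)), test_size=config.val_fraction,
                random_state=split_seed, stratify=outcome.event.astype(int))
        except ValueError:  # an event class too small to stratify on
            idx_tr, idx_val = train_test_split(
                np.arange(len(X)), test_size=config.val_fraction, random_state=split_seed)
        X_val, out_val = X[idx_val], outcome.subset(idx_val)
        X_tr, out_tr = X[idx_tr], outcome.subset(idx_tr)
    else:
        X_tr, out_tr = X, outcome
        X_val, out_val = val

    if out_tr.event.sum() < 2:
        raise ValueError("training data must contain at least 2 events")

    n = len(X_tr)
    best_loss = _val_loss(net, X_val, out_val.time, out_val.event)
    best_w = net.copy_weights()
    history = {"val_loss": [best_loss], "lr": [], "epochs": []}

    for lr in config.stages():
        opt = _Adam([net.W1.shape, net.b1.shape, net.W2.shape, ()], lr)
        stage_best, wait, epochs_run = np.inf, 0, 0
        for _ in range(config.epochs_per_stage):
            perm = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                b = perm[start:start + config.batch_size]
                if out_tr.event[b].sum() < 2:
                    continue
                Xb = X_tr[b]
                # inverted dropout: expectations match the deterministic pass
                if config.input_dropout > 0:
                    gmask = (rng.random((len(b), n_groups)) >= config.input_dropout) / (
                        1 - config.input_dropout)
                    Xb = Xb * gmask[:, input_groups]
                Z1 = Xb @ net.W1 + net.b1
                A1 = _relu(Z1)
                if config.dropout > 0:
                    mask_h = (rng.random(A1.shape) >= config.dropout) / (1 - config.dropout)
                    A1d = A1 * mask_h
                else:
                    mask_h = None
                    A1d = A1
                risk = A1d @ net.W2 + net.b2
                loss, dout = cox_partial_loss_grad(risk, out_tr.time[b], out_tr.event[b])
                if not np.isfinite(loss):
                    raise RuntimeError("non-finite training loss; aborting")
                dW2 = A1d.T @ dout
                db2 = dout.sum()
                dA1 = dout[:, None] * net.W2[None, :]
                if mask_h is not None:
                    dA1 = dA1 * mask_h
                dZ1 = dA1 * (Z1 > 0)
                dW1 = Xb.T @ dZ1
                db1 = dZ1.sum(axis=0)
                new = opt.step([net.W1, net.b1, net.W2, net.b2], [dW1, db1, dW2, db2])
                net.W1, net.b1, net.W2, net.b2 = new[0], new[1], new[2], float(new[3])
            vloss = _val_loss(net, X_val, out_val.time, out_val.event)
            if not np.isfinite(vloss):
                raise RuntimeError("non-finite validation loss; aborting")
            history["val_loss"].append(vloss)
            epochs_run += 1
            if vloss < stage_best - 1e-12:
                stage_best, wait = vloss, 0
            else:
                wait += 1
            if vloss < best_loss:
                best_loss, best_w = vloss, net.copy_weights()
            if wait >= config.patience:
                break
        history["lr"].append(lr)
        history["epochs"].append(epochs_run)
        net.set_weights(best_w)  # each stage restarts from the best weights so far

    net.set_weights(best_w)
    history["best_val_loss"] = best_loss
    return net, history


# ---------------------------------------------------------------------------
# concordance


def concordance(risks, outcome: SurvivalOutcome) -> float:
    """Harrell's C between predicted risk and right-censored outcome.

    Higher risk should pair with shorter survival; risk ties count 0.5.
    Raises ValueError when no comparable pair exists.
    """
    risks = np.asarray(risks, dtype=float)
    if len(risks) != len(outcome):
        raise ValueError("risks and outcome must be aligned")
    try:
        return float(_lifelines_cindex(outcome.time, -risks, outcome.event))
    except ZeroDivisionError as err:
        raise ValueError("concordance undefined: no comparable pairs") from err


# ---------------------------------------------------------------------------
# model / results objects


class CoxRiskNet:
    """Neural proportional-hazards risk model over a feature-expanded cohort.

    Parameters
    ----------
    exog : ExpandedMatrix or ndarray
        Feature-expanded design matrix.
    outcome : SurvivalOutcome
        Right-censored endpoint aligned to the rows of ``exog``.
    """

    def __init__(self, exog, outcome: SurvivalOutcome, colmap=None):
        if isinstance(exog, ExpandedMatrix):
            self.exog = exog.matrix
            self.colmap = exog.colmap
            self.index = exog.index
        else:
            self.exog = np.asarray(exog, dtype=float)
            self.colmap = colmap or [(f"x{i}", "plain") for i in range(self.exog.shape[1])]
            self.index = None
        if len(self.exog) != len(outcome):
            raise ValueError("exog and outcome must have the same length")
        self.outcome = outcome
        self.preprocessor: Preprocessor | None = None

    @classmethod
    def from_cohort(cls, cohort: CohortTable, outcome: SurvivalOutcome,
                    preprocessor: Preprocessor | None = None) -> "CoxRiskNet":
        pp = preprocessor or Preprocessor()
        expanded = pp.transform(cohort) if pp.fitted else pp.fit_transform(cohort)
        model = cls(expanded, outcome)
        model.preprocessor = pp
        return model

    def input_groups(self) -> np.ndarray:
        markers = []
        for m, _ in self.colmap:
            if m not in markers:
                markers.append(m)
        pos = {m: i for i, m in enumerate(markers)}
        return np.array([pos[m] for m, _ in self.colmap])

    def fit(self, config: TrainConfig | None = None,
            val: tuple[np.ndarray, SurvivalOutcome] | None = None) -> "CoxRiskNetResults":
        config = config or TrainConfig()
        net = build_network(self.exog.shape[1], seed=config.seed,
                            hidden_multiplier=config.hidden_multiplier)
        net, history = train(net, self.exog, self.outcome, config, val=val,
                             input_groups=self.input_groups())
        return CoxRiskNetResults(self, net, history, config)


class CoxRiskNetResults:
    """Fitted network plus history, predictions, explanations and summary."""

    def __init__(self, model: CoxRiskNet, net: CoxNet, history: dict, config: TrainConfig):
        self.model = model
        self.net = net
        self.history = history
        self.config = config

    def predict_risk(self, X=None) -> np.ndarray:
        X = self.model.exog if X is None else (X.matrix if isinstance(X, ExpandedMatrix) else X)
        return self.net.predict_risk(X)

    def explain(self, X=None, colmap=None, gamma: float = 0.01):
        from .lrp import explain_cohort

        index = None
        if X is None:
            X, colmap, index = self.model.exog, self.model.colmap, self.model.index
        elif isinstance(X, ExpandedMatrix):
            X, colmap, index = X.matrix, X.colmap, X.index
        elif colmap is None:
            colmap = self.model.colmap
        return explain_cohort(self.net, X, colmap, gamma=gamma, index=index)

    def concordance(self, X=None, outcome: SurvivalOutcome | None = None) -> float:
        outcome = outcome or self.model.outcome
        return concordance(self.predict_risk(X), outcome)

    def summary(self) -> str:
        lines = [
            "Cox partial-likelihood neural network",
            "=" * 46,
            f"patients:            {len(self.model.exog)}",
            f"events:              {int(self.model.outcome.event.sum())} ({self.model.outcome.event_fraction:.1%})",
            f"endpoint:            {self.model.outcome.endpoint}",
            f"input width:         {self.net.input_width}",
            f"hidden width:        {self.net.hidden_width}",
            f"lr stages:           {self.history['lr']}",
            f"epochs per stage:    {self.history['epochs']}",
            f"best val loss:       {self.history['best_val_loss']:.5f}",
            f"train concordance:   {self.concordance():.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Five-fold entity-balanced cross-validation output."""

    pan_cindex: list[float]
    per_entity: pd.DataFrame  # fold, entity, n, events, cindex (NaN if discarded), kept
    test_risks: pd.Series     # combined test-set risks (union of the 5 test splits)
    fold_of: pd.Series        # test-fold index per patient in test_risks
    results: list = field(default_factory=list, repr=False)
    splits: list[dict] = field(default_factory=list, repr=False)  # per-fold train/val/test positions

    @property
    def mean_cindex(self) -> float:
        return float(np.mean(self.pan_cindex))


def merge_small_entities(entity: pd.Series, min_count: int = 5) -> pd.Series:
    counts = entity.value_counts()
    small = counts[counts < min_count].index
    if len(small):
        entity = entity.where(~entity.isin(small), "other")
    return entity


def cross_validate(
    exog,
    outcome: SurvivalOutcome,
    entity: pd.Series,
    config: TrainConfig | None = None,
    n_splits: int = 5,
    min_test_n: int = 10,
    min_test_events: int = 5,
) -> CVResult:
    """Entity-stratified K-fold CV of the risk network.

    Each fold holds out 20% of patients, split in half into validation (for
    early stopping) and test.  Pan-cohort and per-entity test concordances are
    reported; per-entity values are discarded when the entity's test subset
    has fewer than ``min_test_n`` patients or fewer than ``min_test_events``
    events.
    """
    config = config or TrainConfig()
    if isinstance(exog, ExpandedMatrix):
        index = exog.index if exog.index is not None else pd.RangeIndex(len(exog.matrix))
        X = exog.matrix
        colmap = exog.colmap
    else:
        X = np.asarray(exog, dtype=float)
        index = pd.RangeIndex(len(X))
        colmap = None
    strata = merge_small_entities(pd.Series(np.asarray(entity), index=index))

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    pan, rows, risks, folds, results, splits = [], [], [], [], [], []
    for fold, (tr_idx, ho_idx) in enumerate(skf.split(X, strata)):
        ho_strata = strata.iloc[ho_idx]
        try:
            val_idx, te_idx = train_test_split(
                ho_idx, test_size=0.5, random_state=config.seed + fold, stratify=ho_strata
            )
        except ValueError:  # a stratum with a single held-out member
            val_idx, te_idx = train_test_split(ho_idx, test_size=0.5, random_state=config.seed + fold)

        splits.append({"train": tr_idx, "val": np.asarray(val_idx), "test": np.asarray(te_idx)})
        model = CoxRiskNet(X[tr_idx], outcome.subset(tr_idx), colmap=colmap)
        res = model.fit(config, val=(X[val_idx], outcome.subset(val_idx)))
        results.append(res)
        test_out = outcome.subset(te_idx)
        test_risk = res.predict_risk(X[te_idx])
        pan.append(concordance(test_risk, test_out))
        risks.append(pd.Series(test_risk, index=index[te_idx]))
        folds.append(pd.Series(fold, index=index[te_idx]))
        for ent in strata.iloc[te_idx].unique():
            sel = (strata.iloc[te_idx] == ent).to_numpy()
            n, ev = int(sel.sum()), int(test_out.event[sel].sum())
            kept = n >= min_test_n and ev >= min_test_events
            c = np.nan
            if kept:
                try:
                    c = concordance(test_risk[sel], test_out.subset(sel))
                except ValueError:
                    kept = False
            rows.append({"fold": fold, "entity": ent, "n": n, "events": ev,
                         "cindex": c, "kept": kept})

    return CVResult(
        pan_cindex=pan,
        per_entity=pd.DataFrame(rows),
        test_risks=pd.concat(risks).sort_index(),
        fold_of=pd.concat(folds).sort_index(),
        results=results,
        splits=splits,
    )
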