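"""Counterfactual survival estimators.

Four model kinds share one fit/predict contract:

* ``t_cph`` — T-learner with one linear Cox model per treatment arm;
* ``t_deepsurv`` — T-learner with one feed-forward neural Cox model
  (DeepSurv-style) per arm;
* ``bites`` — end-to-end two-head network: a shared encoder and two
  arm-specific risk heads, with a smoothed-optimal-transport (Sinkhorn)
  penalty pulling the two arms' latent representations together;
* ``snb`` — the same two-head architecture built from self-normalizing
  layers (SELU activations, LeCun initialization, alpha dropout).

Every fitted model exposes per-arm log-risk functions g_a(x) and
treatment-specific Breslow baseline cumulative hazards H0_a(t), so the
predicted survival under either scenario is

    S_a(t | x) = exp(-H0_a(t) * exp(g_a(x))),

and the downstream ITE engine never needs to know which estimator
produced the curves.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .coxloss import StepFunction, breslow_baseline, cox_partial_loss_grad
from .ite import SurvivalCurves
from .nets import MLP, Adam
from .sinkhorn import smoothed_ot_divergence_grad

__all__ = ["NetConfig", "FittedRiskModel", "fit_t_cph", "fit_t_deepsurv",
           "fit_balanced_net", "predict_survival", "tune_hyperparameters",
           "save_model", "load_model"]


@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters for the neural estimators.

    ``alpha`` is the balancing strength: the weight of the Sinkhorn
    divergence between the two arms' latents in the total loss.  With
    ``alpha = 0`` a balanced net degenerates to an unbalanced two-head
    network.  ``patience`` counts optimizer steps without validation-loss
    improvement before training stops (the classic 1,000-step rule by
    default).
    """

    shared_layers: tuple = (32,)
    head_layers: tuple = (32,)
    lr: float = 1e-2
    batch_size: int | None = 256        # None = full batch
    alpha: float = 0.0
    dropout: float = 0.0
    activation: str = "rectified"       # "rectified" | "self_normalizing"
    max_iter: int = 3000
    patience: int = 1000
    sinkhorn_eps: float = 0.1
    sinkhorn_iters: int = 20
    val_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("balancing strength alpha must be >= 0")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.max_iter < 1 or self.patience < 1:
            raise ValueError("max_iter and patience must be positive")


@dataclass
class FittedRiskModel:
    """Per-arm log-risk functions plus Breslow baselines (shared contract
    of all four model kinds)."""

    kind: str                                   # t_cph | t_deepsurv | bites | snb
    baselines: dict                             # arm -> StepFunction
    linear_coefs: dict | None = None            # arm -> ndarray (t_cph)
    heads: dict | None = None                   # arm -> MLP (neural kinds)
    encoder: object | None = None               # MLP or None
    feature_names: list | None = None
    metadata: dict = field(default_factory=dict)

    def predict_log_risk(self, arm: int, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.kind == "t_cph":
            return X @ self.linear_coefs[arm]
        h = self.encoder.forward(X) if self.encoder is not None else X
        return self.heads[arm].forward(h)[:, 0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent representation (identity for models without an encoder)."""
        X = np.atleast_2d(np.asarray(X, float))
        return self.encoder.forward(X) if self.encoder is not None else X


# ---------------------------------------------------------------------------
# linear T-learner
# ---------------------------------------------------------------------------

def fit_t_cph(design0, labels0, design1, labels1,
              feature_names=None, penalizer: float = 0.0) -> FittedRiskModel:
    """T-learner with an independent linear Cox fit per treatment arm.

    ``labels`` are ``(times, events)`` tuples.  Constant (zero-variance)
    columns carry no signal and get coefficient 0.  Each arm needs at
    least two events; non-convergence or separation surfaces as a
    ``ValueError`` with the lifelines diagnostic attached.
    """
    coefs, baselines, meta = {}, {}, {}
    for arm, (X, (times, events)) in enumerate(
            [(design0, labels0), (design1, labels1)]):
        X = np.atleast_2d(np.asarray(X, float))
        times = np.asarray(times, float)
        events = np.asarray(events, int)
        if events.sum() < 2:
            raise ValueError(f"arm {arm} has fewer than 2 events")
        keep = X.std(axis=0) > 0
        beta = np.zeros(X.shape[1])
        if keep.any():
            cols = [f"x{j}" for j in np.flatnonzero(keep)]
            df = pd.DataFrame(X[:, keep], columns=cols)
            df["time"], df["event"] = times, events
            cph = CoxPHFitter(penalizer=penalizer)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
            except Exception as exc:   # lifelines raises ConvergenceError etc.
                raise ValueError(
                    f"Cox fit failed in arm {arm}: {exc}") from exc
            beta[keep] = cph.params_.to_numpy()
        coefs[arm] = beta
        baselines[arm] = breslow_baseline(times, events, X @ beta)
        meta[f"arm{arm}_n"] = int(len(times))
    return FittedRiskModel(kind="t_cph", baselines=baselines,
                           linear_coefs=coefs, feature_names=feature_names,
                           metadata=meta)


# ---------------------------------------------------------------------------
# neural training loop shared by t_deepsurv and the balanced nets
# ---------------------------------------------------------------------------

def _val_split(n: int, frac: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(frac * n)))
    return idx[n_val:], idx[:n_val]


def _batch_indices(idx: np.ndarray, batch_size, rng: np.random.Generator):
    if batch_size is None or batch_size >= len(idx):
        while True:
            yield idx
    else:
        while True:
            perm = rng.permutation(idx)
            for s in range(0, len(perm) - batch_size + 1, batch_size):
                yield perm[s:s + batch_size]


def _train_single_net(X, times, events, config: NetConfig,
                      rng: np.random.Generator) -> MLP:
    """One per-arm DeepSurv-style net: minimize the Cox partial loss with
    Adam, early-stopping on a held-out validation fold."""
    n, d = X.shape
    fit_idx, val_idx = _val_split(n, config.val_fraction, rng)
    if events[fit_idx].sum() == 0 or events[val_idx].sum() == 0:
        fit_idx, val_idx = np.arange(n), np.arange(n)   # tiny-data fallback
    dims = [d, *config.shared_layers, *config.head_layers, 1]
    net = MLP(dims, activation=config.activation, dropout=config.dropout,
              rng=rng)
    opt = Adam(net.params, lr=config.lr)
    best_loss, best_params, since_best = np.inf, None, 0
    batches = _batch_indices(fit_idx, config.batch_size, rng)
    for step in range(config.max_iter):
        b = next(batches)
        if events[b].sum() == 0:
            continue
        out = net.forward(X[b], train=True, rng=rng)
        loss, dlr = cox_partial_loss_grad(out[:, 0], times[b], events[b])
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training loss diverged at step {step} (last finite "
                f"validation loss {best_loss:.4g})")
        grads, _ = net.backward(dlr[:, None])
        opt.step(net.params, grads)

        val_out = net.forward(X[val_idx])
        val_loss, _ = cox_partial_loss_grad(val_out[:, 0], times[val_idx],
                                            events[val_idx])
        if val_loss < best_loss - 1e-9:
            best_loss, since_best = val_loss, 0
            best_params = [p.copy() for p in net.params]
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_params is not None:
        net.set_params(best_params)
    net._val_loss = best_loss
    net._stop_step = step + 1
    return net


def fit_t_deepsurv(design0, labels0, design1, labels1,
                   config: NetConfig | None = None,
                   feature_names=None) -> FittedRiskModel:
    """T-learner with one independently trained neural Cox model per arm."""
    if config is None:
        config = NetConfig()
    config = replace(config, activation="rectified")
    config.validate()
    heads, baselines, meta = {}, {}, {"config": config.__dict__ | {}}
    for arm, (X, (times, events)) in enumerate(
            [(design0, labels0), (design1, labels1)]):
        X = np.atleast_2d(np.asarray(X, float))
        times, events = np.asarray(times, float), np.asarray(events, int)
        rng = np.random.default_rng(config.seed + arm)
        net = _train_single_net(X, times, events, config, rng)
        heads[arm] = net
        baselines[arm] = breslow_baseline(times, events,
                                          net.forward(X)[:, 0])
        meta[f"arm{arm}_val_loss"] = float(net._val_loss)
        meta[f"arm{arm}_stop_step"] = int(net._stop_step)
    return FittedRiskModel(kind="t_deepsurv", baselines=baselines,
                           heads=heads, encoder=None,
                           feature_names=feature_names, metadata=meta)


def fit_balanced_net(design, treatment, labels, config: NetConfig | None = None,
                     variant: str = "snb",
                     feature_names=None) -> FittedRiskModel:
    """End-to-end two-head network with a Sinkhorn balancing penalty.

    Total loss = sum over arms of the per-arm Cox partial loss of that
    arm's head on the shared latents, plus ``alpha`` times the debiased
    Sinkhorn divergence between the arms' latent clouds.  ``variant``
    selects the layer family: ``"bites"`` uses rectified units,
    ``"snb"`` self-normalizing units.
    """
    if variant not in ("bites", "snb"):
        raise ValueError(f"variant must be 'bites' or 'snb', got {variant!r}")
    if config is None:
        config = NetConfig()
    config = replace(config, activation=(
        "self_normalizing" if variant == "snb" else "rectified"))
    config.validate()

    X = np.atleast_2d(np.asarray(design, float))
    a = np.asarray(treatment, int)
    times, events = (np.asarray(labels[0], float), np.asarray(labels[1], int))
    n, d = X.shape
    rng = np.random.default_rng(config.seed)

    fit_idx, val_idx = _val_split(n, config.val_fraction, rng)
    for arm in (0, 1):
        if events[fit_idx][a[fit_idx] == arm].sum() == 0 \
                or events[val_idx][a[val_idx] == arm].sum() == 0:
            fit_idx, val_idx = np.arange(n), np.arange(n)
            break

    # empty shared_layers = identity encoder: two heads on the raw design,
    # the direct two-head analogue of the T-learner (requires alpha = 0,
    # since the input representation cannot be moved)
    if len(config.shared_layers) == 0:
        if config.alpha > 0:
            raise ValueError("balancing requires a trainable shared encoder")
        encoder, latent_dim = None, d
    else:
        latent_dim = config.shared_layers[-1]
        encoder = MLP([d, *config.shared_layers], activation=config.activation,
                      dropout=config.dropout, rng=rng)
    heads = {arm: MLP([latent_dim, *config.head_layers, 1],
                      activation=config.activation, dropout=config.dropout,
                      rng=rng) for arm in (0, 1)}
    enc_params = encoder.params if encoder is not None else []
    params = enc_params + heads[0].params + heads[1].params
    opt = Adam(params, lr=config.lr)
    n_enc, n_head = len(enc_params), len(heads[0].params)

    # arm-stratified batches so both arms appear in every step
    per_arm_idx = {arm: fit_idx[a[fit_idx] == arm] for arm in (0, 1)}
    if min(len(v) for v in per_arm_idx.values()) == 0:
        raise ValueError("both treatment arms must be present in the data")
    if config.batch_size is None or config.batch_size >= len(fit_idx):
        arm_batches = None
    else:
        frac1 = len(per_arm_idx[1]) / len(fit_idx)
        b1 = max(2, int(round(config.batch_size * frac1)))
        b0 = max(2, config.batch_size - b1)
        arm_batches = {0: _batch_indices(per_arm_idx[0], b0, rng),
                       1: _batch_indices(per_arm_idx[1], b1, rng)}

    def total_loss_eval(idx):
        h = encoder.forward(X[idx]) if encoder is not None else X[idx]
        loss = 0.0
        for arm in (0, 1):
            m = a[idx] == arm
            if events[idx][m].sum() == 0:
                continue
            out = heads[arm].forward(h[m])[:, 0]
            l, _ = cox_partial_loss_grad(out, times[idx][m], events[idx][m])
            loss += l
        return loss

    best_loss, best_params, since_best = np.inf, None, 0
    step = -1
    for step in range(config.max_iter):
        if arm_batches is None:
            b = fit_idx
        else:
            b = np.concatenate([next(arm_batches[0]), next(arm_batches[1])])
        h = encoder.forward(X[b], train=True, rng=rng) \
            if encoder is not None else X[b]
        mask = {arm: a[b] == arm for arm in (0, 1)}
        dlatent = np.zeros_like(h)
        loss = 0.0
        head_grads = {}
        for arm in (0, 1):
            m = mask[arm]
            if events[b][m].sum() == 0:
                head_grads[arm] = [np.zeros_like(p) for p in heads[arm].params]
                continue
            out = heads[arm].forward(h[m], train=True, rng=rng)
            l, dlr = cox_partial_loss_grad(out[:, 0], times[b][m], events[b][m])
            loss += l
            g, dh = heads[arm].backward(dlr[:, None])
            head_grads[arm] = g
            dlatent[m] += dh
        if config.alpha > 0 and mask[0].sum() > 0 and mask[1].sum() > 0:
            div, g0, g1 = smoothed_ot_divergence_grad(
                h[mask[0]], h[mask[1]], config.sinkhorn_eps,
                config.sinkhorn_iters)
            loss += config.alpha * div
            dlatent[mask[0]] += config.alpha * g0
            dlatent[mask[1]] += config.alpha * g1
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training loss diverged at step {step} (best validation "
                f"loss so far {best_loss:.4g})")
        enc_grads = encoder.backward(dlatent)[0] if encoder is not None else []
        opt.step(params, enc_grads + head_grads[0] + head_grads[1])

        val_loss = total_loss_eval(val_idx)
        if val_loss < best_loss - 1e-9:
            best_loss, since_best = val_loss, 0
            best_params = [p.copy() for p in params]
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    if best_params is not None:
        if encoder is not None:
            encoder.set_params(best_params[:n_enc])
        heads[0].set_params(best_params[n_enc:n_enc + n_head])
        heads[1].set_params(best_params[n_enc + n_head:])

    h_all = encoder.forward(X) if encoder is not None else X
    baselines = {}
    for arm in (0, 1):
        m = a == arm
        lr_arm = heads[arm].forward(h_all[m])[:, 0]
        baselines[arm] = breslow_baseline(times[m], events[m], lr_arm)
    meta = {"config": config.__dict__ | {}, "variant": variant,
            "val_loss": float(best_loss), "stop_step": int(step + 1)}
    return FittedRiskModel(kind=variant, baselines=baselines, heads=heads,
                           encoder=encoder, feature_names=feature_names,
                           metadata=meta)


# ---------------------------------------------------------------------------
# prediction and tuning
# ---------------------------------------------------------------------------

def predict_survival(model: FittedRiskModel, design, grid,
                     patient_ids=None) -> SurvivalCurves:
    """Both arms' survival curves for every patient (factual and
    counterfactual): S_a(t|x) = exp(-H0_a(t) exp(g_a(x)))."""
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted strictly increasing")
    X = np.atleast_2d(np.asarray(design, float))
    if patient_ids is None:
        patient_ids = np.arange(len(X))
    curves = {}
    for arm in (0, 1):
        g = model.predict_log_risk(arm, X)
        H0 = model.baselines[arm](grid)
        curves[arm] = np.exp(-np.outer(np.exp(g), np.ones_like(H0)) * H0)
    return SurvivalCurves(patient_ids=np.asarray(patient_ids), grid=grid,
                          S0=curves[0], S1=curves[1])


def _expand_grid(search_space: dict) -> list[dict]:
    keys = list(search_space)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(search_space[k] for k in keys))]


def tune_hyperparameters(design, treatment, labels, folds, search_space,
                         variant: str = "snb", base_config: NetConfig | None = None,
                         n_draws: int | None = None, seed: int = 0) -> NetConfig:
    """Pick the configuration with the lowest mean validation Cox loss
    across the cross-validation folds.

    ``search_space`` maps NetConfig field names to candidate lists; the
    full grid is evaluated unless ``n_draws`` caps it with a seeded random
    subsample.  Ties break toward the smaller network, then lower alpha.
    """
    if not search_space:
        raise ValueError("search space must be non-empty")
    if base_config is None:
        base_config = NetConfig()
    candidates = _expand_grid(search_space)
    if n_draws is not None and n_draws < len(candidates):
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(candidates), size=n_draws, replace=False)
        candidates = [candidates[i] for i in sorted(pick)]

    X = np.atleast_2d(np.asarray(design, float))
    a = np.asarray(treatment, int)
    times, events = (np.asarray(labels[0], float), np.asarray(labels[1], int))

    def fold_loss(cfg: NetConfig, fit_idx, val_idx) -> float:
        if variant in ("bites", "snb"):
            m = fit_balanced_net(X[fit_idx], a[fit_idx],
                                 (times[fit_idx], events[fit_idx]),
                                 cfg, variant=variant)
        else:
            f0, f1 = fit_idx[a[fit_idx] == 0], fit_idx[a[fit_idx] == 1]
            m = fit_t_deepsurv(X[f0], (times[f0], events[f0]),
                               X[f1], (times[f1], events[f1]), cfg)
        loss = 0.0
        for arm in (0, 1):
            vm = val_idx[a[val_idx] == arm]
            if events[vm].sum() == 0:
                continue
            out = m.predict_log_risk(arm, X[vm])
            l, _ = cox_partial_loss_grad(out, times[vm], events[vm])
            loss += l
        return loss

    results = []
    for overrides in candidates:
        cfg = replace(base_config, **overrides, seed=seed)
        losses = [fold_loss(cfg, f, v) for f, v in folds]
        size = sum(cfg.shared_layers) + sum(cfg.head_layers)
        results.append((float(np.mean(losses)), size, cfg.alpha, overrides, cfg))
    results.sort(key=lambda r: (round(r[0], 10), r[1], r[2]))
    return results[0][4]


# ---------------------------------------------------------------------------
# serialization: single JSON archive
# ---------------------------------------------------------------------------

def save_model(model: FittedRiskModel, path: str) -> None:
    def net_dict(net: MLP) -> dict:
        return {"dims": net.dims, "activation": net.activation,
                "dropout": net.dropout,
                "W": [w.tolist() for w in net.W],
                "b": [b.tolist() for b in net.b]}

    payload = {
        "kind": model.kind,
        "feature_names": model.feature_names,
        "metadata": {k: v for k, v in model.metadata.items()
                     if isinstance(v, (int, float, str, list, dict, type(None)))},
        "baselines": {str(k): v.to_dict() for k, v in model.baselines.items()},
        "linear_coefs": ({str(k): v.tolist()
                          for k, v in model.linear_coefs.items()}
                         if model.linear_coefs else None),
        "heads": ({str(k): net_dict(v) for k, v in model.heads.items()}
                  if model.heads else None),
        "encoder": net_dict(model.encoder) if model.encoder is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> FittedRiskModel:
    with open(path) as fh:
        payload = json.load(fh)

    def net_from(d: dict) -> MLP:
        net = MLP(d["dims"], activation=d["activation"], dropout=d["dropout"])
        net.W = [np.asarray(w) for w in d["W"]]
        net.b = [np.asarray(b) for b in d["b"]]
        return net

    return FittedRiskModel(
        kind=payload["kind"],
        baselines={int(k): StepFunction.from_dict(v)
                   for k, v in payload["baselines"].items()},
        linear_coefs=({int(k): np.asarray(v)
                       for k, v in payload["linear_coefs"].items()}
                      if payload["linear_coefs"] else None),
        heads=({int(k): net_from(v) for k, v in payload["heads"].items()}
               if payload["heads"] else None),
        encoder=net_from(payload["encoder"]) if payload["encoder"] else None,
        feature_names=payload["feature_names"],
        metadata=payload["metadata"],
    )
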