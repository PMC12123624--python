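"""Dataset handling, molecule-level splitting, and the training loop.

The loss is the weighted sum of the squared per-atom energy error and the
squared force-component error (the standard choice for this model family):

    L = w_E · mean_configs ((E_pred − E_ref)/N_atoms)²
      + w_F · mean_components (F_pred − F_ref)²

with defaults w_E = 1, w_F = 10 (eV units) and an optional late-phase
energy up-weighting.

Training is full-batch and deterministic given the seed.  All gas-phase
configurations are merged into one disjoint graph (per-configuration
neighbor lists concatenated with index offsets) so each epoch is a handful
of large vectorized passes.  Parameter gradients of the energy term are a
single reverse-mode pass; the force term needs the mixed second derivative
∂²E/∂x∂θ contracted with the force error, which is evaluated as a central
finite difference of the energy parameter-gradient along the (detached)
force-error direction — O(ε²) accurate while requiring only first-order
reverse passes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np

from .graph import AtomicConfiguration, NeighborList, build_neighbor_list
from .model import (Evaluator, ModelConfig, ModelParameters, _segment_sum,
                    init_parameters)


class TrainingDivergence(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

class LabeledDataset:
    """A list of labeled configurations with molecule identities.

    Every record must carry an energy; force labels are optional but
    flagged.  The molecule key (``info['molecule_key']``) groups conformers
    of the same molecule for leakage-free splitting.
    """

    def __init__(self, records):
        self.records = list(records)
        for i, r in enumerate(self.records):
            if r.energy is None:
                raise ValueError(f"record {i} has no energy label")

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    @property
    def molecule_keys(self):
        return [r.info.get("molecule_key", f"record{i:06d}")
                for i, r in enumerate(self.records)]

    @property
    def has_forces(self) -> bool:
        return all(r.forces is not None for r in self.records)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])

    def elements(self):
        zs = set()
        for r in self.records:
            zs.update(int(z) for z in r.species)
        return tuple(sorted(zs))


def split_by_molecule(dataset: LabeledDataset, fractions=(0.8, 0.1, 0.1),
                      seed: int = 0):
    """Leakage-free split: no molecule key spans two splits.

    Fractions apply to molecule identities (honored to within one
    molecule); conformers follow their molecule.  Deterministic per seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    keys = dataset.molecule_keys
    unique = sorted(set(keys))
    n_splits = sum(1 for f in fractions if f > 0)
    if len(unique) < n_splits:
        raise ValueError(f"only {len(unique)} distinct molecules for "
                         f"{n_splits} splits")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    counts = [int(round(f * len(unique))) for f in fractions[:-1]]
    counts.append(len(unique) - sum(counts))
    # every nonzero-fraction split gets at least one molecule
    for i, f in enumerate(fractions):
        if f > 0 and counts[i] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[i] += 1
    splits, pos = [], 0
    for c in counts:
        chosen = set(order[pos:pos + c])
        pos += c
        idx = [i for i, k in enumerate(keys) if k in chosen]
        splits.append(dataset.subset(idx))
    return tuple(splits)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossSpec:
    """Energy/force weights; optionally an energy up-weighting phase.

    ``schedule = (fraction, factor)`` multiplies the energy weight by
    ``factor`` for the last ``fraction`` of the epochs.
    """

    energy_weight: float = 1.0
    force_weight: float = 10.0
    schedule: tuple | None = None

    def __post_init__(self):
        if self.energy_weight < 0 or self.force_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.energy_weight == 0 and self.force_weight == 0:
            raise ValueError("at least one loss weight must be positive")


def loss(params: ModelParameters, batch, spec: LossSpec,
         model_config: ModelConfig) -> float:
    """Reference (per-configuration) evaluation of the training loss."""
    from .model import forces_and_stress, total_energy
    e_terms, f_sq, n_f = [], 0.0, 0
    for rec in batch:
        if spec.force_weight > 0:
            if rec.forces is None:
                raise ValueError("force weight set but record lacks forces")
            res = forces_and_stress(params, rec, model_config, stress=False)
            d = res.forces - rec.forces
            f_sq += float(np.sum(d * d))
            n_f += d.size
        else:
            res = total_energy(params, rec, model_config)
        e_terms.append(((res.energy - rec.energy) / rec.n_atoms) ** 2)
    out = spec.energy_weight * float(np.mean(e_terms))
    if spec.force_weight > 0:
        out += spec.force_weight * f_sq / n_f
    return out


# ---------------------------------------------------------------------------
# merged-graph batch
# ---------------------------------------------------------------------------

class MergedBatch:
    """All (gas-phase) configurations of a dataset as one disjoint graph."""

    def __init__(self, records, model_config: ModelConfig):
        if any(any(r.pbc) for r in records):
            raise ValueError("the merged training path is gas-phase only")
        self.model_config = model_config
        self.n_configs = len(records)
        species, positions, edges_i, edges_j = [], [], [], []
        self.config_of_atom = []
        self.n_atoms_per = np.array([r.n_atoms for r in records])
        offset = 0
        for ci, r in enumerate(records):
            nl = build_neighbor_list(r, model_config.r_cut)
            species.append(r.species)
            positions.append(r.positions)
            edges_i.append(nl.idx_i + offset)
            edges_j.append(nl.idx_j + offset)
            self.config_of_atom.extend([ci] * r.n_atoms)
            offset += r.n_atoms
        self.config_of_atom = np.array(self.config_of_atom)
        self.merged = AtomicConfiguration(
            np.concatenate(species), np.vstack(positions))
        ii = np.concatenate(edges_i)
        jj = np.concatenate(edges_j)
        shifts = np.zeros((len(ii), 3), dtype=int)
        self.nl = NeighborList(ii, jj, shifts, model_config.r_cut)
        self.e_ref = np.array([r.energy for r in records])
        self.f_ref = (np.vstack([r.forces for r in records])
                      if all(r.forces is not None for r in records) else None)
        self.n_total = offset

    def config_energies(self, site_energies: np.ndarray) -> np.ndarray:
        return _segment_sum(site_energies, self.config_of_atom,
                            self.n_configs)


def _batch_eval(ev: Evaluator, params, batch: MergedBatch, geom=None):
    """Energies per config and forces on the merged graph."""
    if geom is None:
        geom = ev.compute_geometry(batch.merged, nl=batch.nl)
    cache = ev.forward(params, batch.merged, geom=geom)
    e_cfg = batch.config_energies(cache["site_energies"])
    grad_pos, _, _ = ev.backward(params, cache)
    return e_cfg, -grad_pos, cache


def batch_rmse(ev: Evaluator, params, batch: MergedBatch, geom=None):
    """(energy RMSE meV/atom, force RMSE meV/Å) on a merged batch."""
    e_cfg, f_pred, _ = _batch_eval(ev, params, batch, geom)
    de = (e_cfg - batch.e_ref) / batch.n_atoms_per
    e_rmse = float(np.sqrt(np.mean(de ** 2))) * 1000.0
    f_rmse = float("nan")
    if batch.f_ref is not None:
        df = f_pred - batch.f_ref
        f_rmse = float(np.sqrt(np.mean(df ** 2))) * 1000.0
    return e_rmse, f_rmse


def _loss_and_grad(ev: Evaluator, params: ModelParameters,
                   batch: MergedBatch, spec: LossSpec, geom,
                   fd_eps_scale: float = 1e-3):
    """Full-batch loss and analytic parameter gradient.

    The force-term gradient uses a central finite difference of the
    energy parameter-gradient along the detached force-error direction.
    """
    cfg = ev.config
    cache = ev.forward(params, batch.merged, geom=geom)
    e_cfg = batch.config_energies(cache["site_energies"])
    de = e_cfg - batch.e_ref
    L = spec.energy_weight * float(np.mean((de / batch.n_atoms_per) ** 2))
    # per-site adjoint of the energy term
    s_E = (2.0 * spec.energy_weight * de
           / (batch.n_configs * batch.n_atoms_per ** 2))[batch.config_of_atom]
    use_forces = spec.force_weight > 0
    if use_forces:
        if batch.f_ref is None:
            raise ValueError("force weight set but batch lacks force labels")
        grad_pos, _, _ = ev.backward(params, cache, pos_grads=True)
        df = -grad_pos - batch.f_ref
        L += spec.force_weight * float(np.mean(df ** 2))
        v = 2.0 * spec.force_weight * df / df.size
        eps = fd_eps_scale / max(np.abs(v).max(), 1e-30)
        # central difference of grad_θ E along v, folded into the seeds
        _, _, g_plus = _param_grad_at(ev, params, batch,
                                      batch.merged.positions + eps * v)
        _, _, g_minus = _param_grad_at(ev, params, batch,
                                       batch.merged.positions - eps * v)
        _, _, g0 = ev.backward(params, cache, dE_sites=s_E,
                               param_grads=True, pos_grads=False)
        grads = {k: g0[k] - (g_plus[k] - g_minus[k]) / (2.0 * eps)
                 for k in g0}
    else:
        _, _, grads = ev.backward(params, cache, dE_sites=s_E,
                                  param_grads=True, pos_grads=False)
    if not np.isfinite(L):
        raise TrainingDivergence(f"non-finite loss: {L!r}")
    return L, grads


def _param_grad_at(ev: Evaluator, params, batch: MergedBatch, positions):
    shifted = AtomicConfiguration(batch.merged.species, positions)
    geom = ev.compute_geometry(shifted, nl=batch.nl)
    cache = ev.forward(params, shifted, geom=geom)
    return (None, None, ev.backward(params, cache, param_grads=True,
                                    pos_grads=False)[2])


# ---------------------------------------------------------------------------
# optimizer and training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizerSettings:
    """Optimizer choice and schedule.

    ``method='adam'`` (default): full-batch Adam with cosine learning-rate
    decay and global gradient clipping.  ``method='lbfgs'``: scipy L-BFGS
    on the full-batch loss — much deeper convergence on small (overfit)
    sets; ``epochs`` then counts L-BFGS iterations.
    """

    method: str = "adam"
    learning_rate: float = 1e-2
    final_lr_fraction: float = 1e-2
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    clip_norm: float = 10.0
    epochs: int = 300

    def __post_init__(self):
        if self.method not in ("adam", "lbfgs"):
            raise ValueError(f"unknown optimizer method {self.method!r}")


@dataclass
class TrainingResult:
    """Best-validation parameters plus the full per-epoch history."""

    params: ModelParameters
    model_config: ModelConfig
    history: list
    best_epoch: int
    seed: int

    def summary(self) -> str:
        last = self.history[-1] if self.history else {}
        best = self.history[self.best_epoch] if self.history else {}
        lines = [
            "Training summary",
            "================",
            f"epochs run          : {len(self.history)}",
            f"trainable parameters: {self.params.n_trainable}",
            f"seed                : {self.seed}",
            f"best epoch          : {self.best_epoch}",
            "",
            f"{'':>16}{'train loss':>14}{'valid E (meV/at)':>18}"
            f"{'valid F (meV/Å)':>17}",
            f"{'final':>16}{last.get('loss', float('nan')):>14.6g}"
            f"{last.get('valid_e_rmse', float('nan')):>18.4g}"
            f"{last.get('valid_f_rmse', float('nan')):>17.4g}",
            f"{'best valid':>16}{best.get('loss', float('nan')):>14.6g}"
            f"{best.get('valid_e_rmse', float('nan')):>18.4g}"
            f"{best.get('valid_f_rmse', float('nan')):>17.4g}",
        ]
        return "\n".join(lines)

    def history_to_csv(self, path):
        if not self.history:
            return
        cols = list(self.history[0].keys())
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.history)


def _clip(grads: dict, clip_norm: float):
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if clip_norm and total > clip_norm:
        scale = clip_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads, total


def estimate_avg_neighbors(records, r_cut: float) -> float:
    counts = []
    for r in records:
        nl = build_neighbor_list(r, r_cut)
        counts.append(nl.n_edges / r.n_atoms)
    return float(max(np.mean(counts), 1.0))


def train(train_set: LabeledDataset, valid_set: LabeledDataset,
          model_config: ModelConfig, loss_spec: LossSpec | None = None,
          optimizer: OptimizerSettings | None = None, seed: int = 0,
          initial_params: ModelParameters | None = None,
          callback=None) -> TrainingResult:
    """Full-batch Adam training; returns best-validation parameters.

    Deterministic given ``seed`` (initialization and all updates).  The
    average neighbor count used for the model's pooling normalization is
    estimated from the training set unless already set by the caller.
    """
    loss_spec = loss_spec or LossSpec()
    opt = optimizer or OptimizerSettings()
    if model_config.avg_num_neighbors is None:
        model_config = replace(
            model_config,
            avg_num_neighbors=estimate_avg_neighbors(
                train_set.records, model_config.r_cut))
    ev = Evaluator(model_config)
    params = (initial_params.copy() if initial_params is not None
              else init_parameters(model_config, seed))
    train_batch = MergedBatch(train_set.records, model_config)
    valid_batch = MergedBatch(valid_set.records, model_config)
    geom = ev.compute_geometry(train_batch.merged, nl=train_batch.nl)
    vgeom = ev.compute_geometry(valid_batch.merged, nl=valid_batch.nl)

    # weights of the final training phase, used for best-model selection so
    # the selection criterion matches the objective actually optimized last
    final_spec = loss_spec
    if loss_spec.schedule is not None:
        final_spec = replace(loss_spec,
                             energy_weight=loss_spec.energy_weight
                             * loss_spec.schedule[1])

    def valid_score(v_e, v_f):
        s = final_spec.energy_weight * (v_e / 1000.0) ** 2
        if np.isfinite(v_f):
            s += final_spec.force_weight * (v_f / 1000.0) ** 2
        return s

    history = []
    best = {"epoch": -1, "score": np.inf, "params": params.copy()}

    if opt.method == "lbfgs":
        params = _train_lbfgs(ev, params, train_batch, loss_spec, final_spec,
                              opt, geom, valid_batch, vgeom, history,
                              callback)
        v_e, v_f = batch_rmse(ev, params, valid_batch, vgeom)
        best.update(epoch=len(history) - 1, params=params,
                    score=valid_score(v_e, v_f))
        return TrainingResult(params=params, model_config=model_config,
                              history=history,
                              best_epoch=max(len(history) - 1, 0), seed=seed)

    keys = params.trainable_keys
    mom = {k: np.zeros_like(params[k]) for k in keys}
    vel = {k: np.zeros_like(params[k]) for k in keys}
    for epoch in range(opt.epochs):
        spec_now = loss_spec
        if loss_spec.schedule is not None:
            frac, factor = loss_spec.schedule
            if epoch >= frac * opt.epochs:
                spec_now = replace(loss_spec,
                                   energy_weight=loss_spec.energy_weight
                                   * factor)
        L, grads = _loss_and_grad(ev, params, train_batch, spec_now, geom)
        grads, gnorm = _clip(grads, opt.clip_norm)
        # cosine learning-rate decay
        lr = opt.learning_rate * (
            opt.final_lr_fraction + (1 - opt.final_lr_fraction)
            * 0.5 * (1 + np.cos(np.pi * epoch / max(1, opt.epochs - 1))))
        t = epoch + 1
        for k in keys:
            mom[k] = opt.beta1 * mom[k] + (1 - opt.beta1) * grads[k]
            vel[k] = opt.beta2 * vel[k] + (1 - opt.beta2) * grads[k] ** 2
            mhat = mom[k] / (1 - opt.beta1 ** t)
            vhat = vel[k] / (1 - opt.beta2 ** t)
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + opt.eps)
        v_e, v_f = batch_rmse(ev, params, valid_batch, vgeom)
        score = valid_score(v_e, v_f)
        entry = {"epoch": epoch, "loss": L, "lr": lr, "grad_norm": gnorm,
                 "valid_e_rmse": v_e, "valid_f_rmse": v_f}
        history.append(entry)
        if score < best["score"]:
            best.update(epoch=epoch, score=score, params=params.copy())
        if callback is not None:
            callback(entry)
    result_params = best["params"] if best["epoch"] >= 0 else params
    return TrainingResult(params=result_params, model_config=model_config,
                          history=history,
                          best_epoch=max(best["epoch"], 0), seed=seed)


def _train_lbfgs(ev, params, train_batch, loss_spec, final_spec, opt, geom,
                 valid_batch, vgeom, history, callback):
    """Two-phase L-BFGS (base weights, then up-weighted energies)."""
    from scipy.optimize import minimize
    keys = params.trainable_keys
    phases = [(loss_spec, opt.epochs)]
    if loss_spec.schedule is not None:
        frac, _ = loss_spec.schedule
        phases = [(loss_spec, int(frac * opt.epochs)),
                  (final_spec, opt.epochs - int(frac * opt.epochs))]
    current = params
    for spec_now, n_iter in phases:
        if n_iter <= 0:
            continue

        def fun(x, spec=spec_now):
            p = current.unflatten(x)
            L, g = _loss_and_grad(ev, p, train_batch, spec, geom)
            return L, np.concatenate([g[k].ravel() for k in keys])

        def record(x):
            history.append({"epoch": len(history), "loss": np.nan,
                            "lr": np.nan, "grad_norm": np.nan,
                            "valid_e_rmse": np.nan, "valid_f_rmse": np.nan})

        res = minimize(fun, current.flatten(), jac=True, method="L-BFGS-B",
                       callback=record,
                       options={"maxiter": n_iter, "maxfun": 3 * n_iter,
                                "ftol": 1e-18, "gtol": 1e-14})
        current = current.unflatten(res.x)
    v_e, v_f = batch_rmse(ev, current, valid_batch, vgeom)
    L_final, _ = _loss_and_grad(ev, current, train_batch, final_spec, geom)
    entry = {"epoch": len(history), "loss": L_final, "lr": np.nan,
             "grad_norm": np.nan, "valid_e_rmse": v_e, "valid_f_rmse": v_f}
    history.append(entry)
    if callback is not None:
        callback(entry)
    return current
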