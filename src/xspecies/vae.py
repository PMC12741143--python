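"""Variational autoencoder for cross-species expression modelling.

The model follows the scGen-style architecture: encoder and decoder are
mirrored MLPs with two hidden layers, each followed by batch normalization,
leaky ReLU (negative slope 0.01) and dropout; the encoder parameterizes the
mean and log-variance of a diagonal-Gaussian posterior over a low-dimensional
latent space. Training minimizes per-element reconstruction MSE on the
log-normalized layer plus a weighted KL divergence to the standard-normal
prior, with early stopping on validation loss. A ``decoder_mode="linear"``
option replaces the decoder by a single affine map (the linearly-decoded
variant), trading capacity for a directly interpretable latent-to-gene map.

API shape: ``ExpressionVAE(X, gene_ids, config)`` is the model;
``.fit()`` returns a :class:`VAEResults` carrying the trained parameters,
the per-epoch loss log, and encode/decode methods.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, normalize_log1p
from .nn import Adam, BatchNorm, Dense, Dropout, LeakyReLU, Sequential

__all__ = ["VAEConfig", "ExpressionVAE", "VAEResults", "select_hvg", "grid_search"]

MIN_CELLS_PER_TYPE = 1_000  # cell types below this are skipped for per-type models


@dataclass
class VAEConfig:
    latent_dim: int = 10
    hidden_sizes: tuple[int, ...] = (800, 800)
    leaky_relu_slope: float = 0.01
    dropout_p: float = 0.2
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 25
    kl_weight: float = 5e-5
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    decoder_mode: str = "nonlinear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0,1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.decoder_mode not in ("nonlinear", "linear"):
            raise ValueError("decoder_mode must be 'nonlinear' or 'linear'")


def _build_networks(n_genes: int, config: VAEConfig, rng: np.random.Generator):
    h = list(config.hidden_sizes)
    enc_layers = []
    widths = [n_genes] + h
    for i in range(len(h)):
        enc_layers += [
            Dense(widths[i], widths[i + 1], rng),
            BatchNorm(widths[i + 1]),
            LeakyReLU(config.leaky_relu_slope),
            Dropout(config.dropout_p, rng),
        ]
    enc_layers.append(Dense(widths[-1], 2 * config.latent_dim, rng))
    encoder = Sequential(enc_layers)

    if config.decoder_mode == "linear":
        decoder = Sequential([Dense(config.latent_dim, n_genes, rng)])
    else:
        dec_layers = []
        widths = [config.latent_dim] + h[::-1]
        for i in range(len(h)):
            dec_layers += [
                Dense(widths[i], widths[i + 1], rng),
                BatchNorm(widths[i + 1]),
                LeakyReLU(config.leaky_relu_slope),
                Dropout(config.dropout_p, rng),
            ]
        dec_layers.append(Dense(widths[-1], n_genes, rng))
        decoder = Sequential(dec_layers)
    return encoder, decoder


class ExpressionVAE:
    """VAE model over a fixed gene space; ``fit`` returns a results object."""

    def __init__(self, X: np.ndarray, gene_ids, config: VAEConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.gene_ids = list(gene_ids)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.gene_ids):
            raise ValueError("X must be cells x genes over gene_ids")
        self.config = config or VAEConfig()

    @classmethod
    def from_count_matrix(cls, cm: CountMatrix, config: VAEConfig | None = None):
        X = cm.normalized if cm.normalized is not None else normalize_log1p(cm.counts)
        return cls(X, cm.gene_ids, config)

    def fit(self, X_val: np.ndarray | None = None, verbose: bool = False) -> "VAEResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        encoder, decoder = _build_networks(len(self.gene_ids), cfg, rng)
        params = encoder.params + decoder.params
        grads = encoder.grads + decoder.grads
        opt = Adam(params, grads, lr=cfg.learning_rate)

        if X_val is None:
            n = self.X.shape[0]
            perm = rng.permutation(n)
            n_val = max(1, int(round(cfg.val_fraction * n)))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            X_train, X_val = self.X[train_idx], self.X[val_idx]
        else:
            X_train = self.X
            X_val = np.asarray(X_val, dtype=float)

        d = cfg.latent_dim
        log_rows = []
        best_val = np.inf
        best_params = None
        best_epoch = 0
        since_best = 0

        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(X_train.shape[0])
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, len(order), cfg.batch_size):
                batch = X_train[order[lo:lo + cfg.batch_size]]
                B = batch.shape[0]
                if B < 2:  # batch-norm needs at least 2 samples
                    continue
                out = encoder.forward(batch, train=True)
                mu, logvar = out[:, :d], out[:, d:]
                logvar = np.clip(logvar, -10.0, 10.0)
                eps = rng.standard_normal(mu.shape)
                z = mu + eps * np.exp(0.5 * logvar)
                xhat = decoder.forward(z, train=True)

                G = batch.shape[1]
                recon = float(np.mean((xhat - batch) ** 2))
                kl = float(np.mean(-0.5 * np.sum(1 + logvar - mu ** 2 - np.exp(logvar), axis=1)))
                loss = recon + cfg.kl_weight * kl
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} (recon={recon}, kl={kl})")
                epoch_loss += loss
                n_batches += 1

                dxhat = 2.0 * (xhat - batch) / (B * G)
                dz = decoder.backward(dxhat)
                dmu = dz + cfg.kl_weight * mu / B
                dlogvar = (dz * eps * 0.5 * np.exp(0.5 * logvar)
                           + cfg.kl_weight * 0.5 * (np.exp(logvar) - 1.0) / B)
                encoder.backward(np.hstack([dmu, dlogvar]))
                opt.step()

            train_loss = epoch_loss / max(n_batches, 1)
            val_loss = _eval_loss(encoder, decoder, X_val, d, cfg.kl_weight)
            log_rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
            if verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.5f}  val {val_loss:.5f}")
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_epoch = epoch
                best_params = [p.copy() for p in params]
                best_bn = _bn_state(encoder, decoder)
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break

        if best_params is not None:
            for p, bp in zip(params, best_params):
                p[...] = bp
            _restore_bn(encoder, decoder, best_bn)
        return VAEResults(encoder=encoder, decoder=decoder, config=cfg,
                          gene_ids=self.gene_ids, log=pd.DataFrame(log_rows),
                          best_epoch=best_epoch)


def _eval_loss(encoder, decoder, X, d, kl_weight) -> float:
    out = encoder.forward(X, train=False)
    mu, logvar = out[:, :d], np.clip(out[:, d:], -10.0, 10.0)
    xhat = decoder.forward(mu, train=False)
    recon = float(np.mean((xhat - X) ** 2))
    kl = float(np.mean(-0.5 * np.sum(1 + logvar - mu ** 2 - np.exp(logvar), axis=1)))
    return recon + kl_weight * kl


def _bn_state(encoder, decoder):
    state = []
    for net in (encoder, decoder):
        for lay in net.layers:
            if isinstance(lay, BatchNorm):
                state.append((lay.running_mean.copy(), lay.running_var.copy()))
    return state


def _restore_bn(encoder, decoder, state) -> None:
    it = iter(state)
    for net in (encoder, decoder):
        for lay in net.layers:
            if isinstance(lay, BatchNorm):
                mean, var = next(it)
                lay.running_mean[...] = mean
                lay.running_var[...] = var


@dataclass
class VAEResults:
    """Trained VAE: parameters, loss log, and deterministic encode/decode."""

    encoder: Sequential
    decoder: Sequential
    config: VAEConfig
    gene_ids: list[str]
    log: pd.DataFrame
    best_epoch: int

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.encoder.params + self.decoder.params))

    def _check_genes(self, X: np.ndarray, gene_ids=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"input has {X.shape[1]} genes, model expects {len(self.gene_ids)}")
        if gene_ids is not None and list(gene_ids) != self.gene_ids:
            missing = sorted(set(self.gene_ids) - set(gene_ids))
            raise ValueError(f"gene set mismatch; missing from input: {missing[:10]}")
        return X

    def encode(self, X: np.ndarray, gene_ids=None) -> np.ndarray:
        """Posterior mean mu(x); deterministic (inference mode)."""
        X = self._check_genes(X, gene_ids)
        out = self.encoder.forward(X, train=False)
        return out[:, : self.config.latent_dim]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Reconstruction on the log-normalized scale, clipped below at 0."""
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[None, :]
        if Z.shape[1] != self.config.latent_dim:
            raise ValueError("latent width mismatch")
        return np.clip(self.decoder.forward(Z, train=False), 0.0, None)

    def decode_raw(self, Z: np.ndarray) -> np.ndarray:
        """Decoder output without the non-negativity clip (linearity checks)."""
        Z = np.asarray(Z, dtype=float)
        return self.decoder.forward(Z if Z.ndim == 2 else Z[None, :], train=False)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    def summary(self) -> str:
        last = self.log.iloc[-1] if len(self.log) else {"train_loss": float("nan"),
                                                        "val_loss": float("nan")}
        lines = [
            "Expression VAE results",
            "=" * 40,
            f"genes:            {len(self.gene_ids)}",
            f"latent dim:       {self.config.latent_dim}",
            f"hidden sizes:     {tuple(self.config.hidden_sizes)}",
            f"decoder mode:     {self.config.decoder_mode}",
            f"parameters:       {self.n_parameters}",
            f"epochs run:       {len(self.log)} (best {self.best_epoch})",
            f"final train loss: {last['train_loss']:.6f}",
            f"final val loss:   {last['val_loss']:.6f}",
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        blob = {}
        for i, p in enumerate(self.encoder.params):
            blob[f"enc_{i}"] = p
        for i, p in enumerate(self.decoder.params):
            blob[f"dec_{i}"] = p
        for j, (m, v) in enumerate(_bn_state(self.encoder, self.decoder)):
            blob[f"bn_mean_{j}"], blob[f"bn_var_{j}"] = m, v
        np.savez(out_dir / "params.npz", **blob)
        cfg = asdict(self.config)
        cfg["hidden_sizes"] = list(cfg["hidden_sizes"])
        (out_dir / "config.json").write_text(json.dumps(cfg, indent=2), encoding="utf-8")
        (out_dir / "genes.txt").write_text("".join(g + "\n" for g in self.gene_ids),
                                           encoding="utf-8")
        self.log.to_csv(out_dir / "loss_log.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, out_dir) -> "VAEResults":
        out_dir = Path(out_dir)
        cfg_d = json.loads((out_dir / "config.json").read_text(encoding="utf-8"))
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        config = VAEConfig(**cfg_d)
        gene_ids = [l for l in (out_dir / "genes.txt").read_text(encoding="utf-8").splitlines() if l]
        rng = np.random.default_rng(config.seed)
        encoder, decoder = _build_networks(len(gene_ids), config, rng)
        blob = np.load(out_dir / "params.npz")
        for i, p in enumerate(encoder.params):
            p[...] = blob[f"enc_{i}"]
        for i, p in enumerate(decoder.params):
            p[...] = blob[f"dec_{i}"]
        j = 0
        for net in (encoder, decoder):
            for lay in net.layers:
                if isinstance(lay, BatchNorm):
                    lay.running_mean[...] = blob[f"bn_mean_{j}"]
                    lay.running_var[...] = blob[f"bn_var_{j}"]
                    j += 1
        log = pd.read_csv(out_dir / "loss_log.tsv", sep="\t")
        return cls(encoder=encoder, decoder=decoder, config=config,
                   gene_ids=gene_ids, log=log, best_epoch=int(log["val_loss"].idxmin() + 1)
                   if len(log) else 0)


def select_hvg(counts_by_species: dict[str, CountMatrix], n_per_species: int = 2_000,
               n_bins: int = 20) -> list[str]:
    """Union of per-species highly variable genes, sorted.

    Per species, genes are ranked by normalized dispersion: the dispersion
    (variance/mean of log-normalized expression) standardized within
    mean-expression bins. Zero-variance genes are never selected.
    """
    import warnings

    union: set[str] = set()
    for species, cm in counts_by_species.items():
        X = cm.normalized if cm.normalized is not None else normalize_log1p(cm.counts)
        mean = X.mean(axis=0)
        var = X.var(axis=0)
        ok = var > 0
        if ok.sum() <= n_per_species:
            if ok.sum() < n_per_species:
                warnings.warn(f"{species}: only {int(ok.sum())} variable genes "
                              f"(requested {n_per_species}); returning all")
            union |= {g for g, o in zip(cm.gene_ids, ok) if o}
            continue
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
        bins = pd.qcut(pd.Series(mean[ok]), q=min(n_bins, ok.sum()), duplicates="drop")
        z = pd.Series(disp[ok]).groupby(bins, observed=True).transform(
            lambda s: (s - s.mean()) / (s.std(ddof=0) if s.std(ddof=0) > 0 else 1.0))
        genes_ok = np.asarray(cm.gene_ids)[ok]
        order = np.argsort(-z.to_numpy(), kind="stable")
        union |= set(genes_ok[order[:n_per_species]].tolist())
    return sorted(union)


def grid_search(X: np.ndarray, gene_ids, latent_grid, batch_grid,
                n_cells: int = 1_000, seed: int = 0,
                base_config: VAEConfig | None = None):
    """Hyperparameter search over (latent_dim, batch_size) by held-out MSE.

    A random subsample of ``n_cells`` is split 80/20 into train/test; one
    model per grid point is trained on the train part and scored by test
    reconstruction MSE. Returns (best_point, table).
    """
    latent_grid, batch_grid = list(latent_grid), list(batch_grid)
    if not latent_grid or not batch_grid:
        raise ValueError("grid must be non-empty")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(X.shape[0])[: min(n_cells, X.shape[0])]
    n_test = max(1, int(round(0.2 * len(idx))))
    test_idx, train_idx = idx[:n_test], idx[n_test:]
    rows = []
    base = base_config or VAEConfig()
    for ld in latent_grid:
        for bs in batch_grid:
            cfg = copy.deepcopy(base)
            cfg.latent_dim, cfg.batch_size, cfg.seed = ld, bs, seed
            res = ExpressionVAE(X[train_idx], gene_ids, cfg).fit()
            mse = float(np.mean((res.reconstruct(X[test_idx]) - X[test_idx]) ** 2))
            rows.append({"latent_dim": ld, "batch_size": bs, "test_mse": mse})
    table = pd.DataFrame(rows)
    best = table.loc[table["test_mse"].idxmin()]
    return (int(best["latent_dim"]), int(best["batch_size"])), table
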