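"""Supervised discriminant signatures: PLS-DA and multi-block integration.

Single-block PLS-DA is a NIPALS PLS2 regression of the autoscaled feature
matrix on the centered one-hot class matrix, with mixOmics-style per-component
sparsity (``keep`` largest-magnitude weights retained, the rest zeroed) and
classic regression deflation.  The default number of latent components is
``n_classes − 1``.

Multi-block PLS-DA (DIABLO-style) alternates sGCCA weight updates that
maximize the design-weighted sum of covariances between block scores and the
class block, giving per-block score vectors whose consensus (average) score
space is used for centroid-distance classification.  ``tune_cv`` grids over
candidate sparsity/components with stratified 5-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns), list(X.index)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])], list(range(X.shape[0]))


def _one_hot(y):
    classes = sorted(pd.unique(pd.Series(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    Y = np.zeros((len(y), len(classes)))
    for i, label in enumerate(y):
        Y[i, classes.index(label)] = 1.0
    return Y - Y.mean(axis=0), classes


def _sparsify(w: np.ndarray, keep: int | None) -> np.ndarray:
    if keep is None or keep >= w.size:
        return w
    keep = max(int(keep), 1)
    order = np.argsort(-np.abs(w), kind="stable")
    out = np.zeros_like(w)
    out[order[:keep]] = w[order[:keep]]
    return out


def _normalize(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def _block_nipals(blocks: list[np.ndarray], Y: np.ndarray, n_components: int,
                  keeps: list[list[int | None]], design: np.ndarray,
                  max_iter: int = 500, tol: float = 1e-9):
    """Shared engine: sparse NIPALS over one or more X blocks and a class block.

    Returns per-block weights/scores/loadings plus class-side loadings and the
    per-component explained class variance.  With a single block this is exactly
    sparse PLS2.
    """
    B = len(blocks)
    Xs = [X.copy() for X in blocks]
    Yd = Y.copy()
    weights = [np.zeros((X.shape[1], n_components)) for X in Xs]
    scores = [np.zeros((X.shape[0], n_components)) for X in Xs]
    loadings = [np.zeros((X.shape[1], n_components)) for X in Xs]
    y_loadings = np.zeros((Y.shape[1], n_components))
    ss_y = np.zeros(n_components)

    for a in range(n_components):
        # init from the class column with the largest variance (deterministic)
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if not np.any(u):
            u = Yd[:, 0] + 1e-12
        t_y = _normalize(u) * np.linalg.norm(u)
        w_blocks = []
        t_blocks = []
        for j in range(B):
            w = _sparsify(_normalize(Xs[j].T @ t_y), keeps[j][a])
            w = _normalize(w)
            w_blocks.append(w)
            t_blocks.append(Xs[j] @ w)
        # refresh the class-side score so the first sweep makes progress
        zy0 = np.zeros(Y.shape[0])
        for j in range(B):
            zy0 = zy0 + design[j, B] * t_blocks[j]
        c = _normalize(Yd.T @ zy0)
        t_y = Yd @ c
        for _ in range(max_iter):
            w_prev = [w.copy() for w in w_blocks]
            for j in range(B):
                z = design[j, B] * t_y
                for k in range(B):
                    if k != j and design[j, k] != 0:
                        z = z + design[j, k] * t_blocks[k]
                w = _sparsify(_normalize(Xs[j].T @ z), keeps[j][a])
                w_blocks[j] = _normalize(w)
                t_blocks[j] = Xs[j] @ w_blocks[j]
            zy = np.zeros(Y.shape[0])
            for j in range(B):
                zy = zy + design[j, B] * t_blocks[j]
            c = _normalize(Yd.T @ zy)
            t_y = Yd @ c
            delta = sum(np.linalg.norm(w_blocks[j] - w_prev[j]) for j in range(B))
            if delta < tol:
                break
        t_bar = np.mean(t_blocks, axis=0)
        denom = float(t_bar @ t_bar)
        q = (Yd.T @ t_bar / denom) if denom > 0 else np.zeros(Y.shape[1])
        ss_y[a] = denom * float(q @ q)
        for j in range(B):
            tj = t_blocks[j]
            dj = float(tj @ tj)
            pj = (Xs[j].T @ tj / dj) if dj > 0 else np.zeros(Xs[j].shape[1])
            weights[j][:, a] = w_blocks[j]
            scores[j][:, a] = tj
            loadings[j][:, a] = pj
            Xs[j] = Xs[j] - np.outer(tj, pj)
        y_loadings[:, a] = q
        Yd = Yd - np.outer(t_bar, q)
    return weights, scores, loadings, y_loadings, ss_y


def _rotation(W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """X-score rotation W (PᵀW)⁻¹ so new data project through the deflation."""
    return W @ np.linalg.pinv(P.T @ W)


@dataclass
class _Scaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, scale: bool) -> "_Scaler":
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
        std = np.where(std > 0, std, 1.0)
        return cls(mean, std)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def _keep_schedule(keep, n_components, n_features):
    """Normalize a keep spec (None | int | per-component list) per block."""
    if keep is None:
        return [None] * n_components
    if np.isscalar(keep):
        return [min(int(keep), n_features)] * n_components
    ks = list(keep)
    if len(ks) < n_components:
        ks = ks + [ks[-1]] * (n_components - len(ks))
    return [None if k is None else min(int(k), n_features) for k in ks[:n_components]]


class PLSDA:
    """Sparse PLS discriminant analysis model.

    Parameters
    ----------
    X : (n_samples, n_features) DataFrame or array
    y : class labels, one per sample
    n_components : int, default ``n_classes − 1``
    keep_per_component : int or per-component list, optional
        Number of largest-magnitude weights retained per component
        (``None`` keeps all; a value above ``n_features`` keeps all).
    scale : bool
        Autoscale features to unit variance (default True; activity/RADDi
        matrices are conventionally fitted unscaled).
    """

    def __init__(self, X, y, n_components: int | None = None,
                 keep_per_component=None, scale: bool = True,
                 max_iter: int = 500, tol: float = 1e-9):
        self.X, self.feature_names, self.sample_names = _as_matrix(X)
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; impute first")
        self.y = list(y)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.Y, self.classes_ = _one_hot(self.y)
        self.n_components = (n_components if n_components is not None
                             else len(self.classes_) - 1)
        self.keep = keep_per_component
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> "PLSDAResults":
        scaler = _Scaler.fit(self.X, self.scale)
        Xs = scaler.apply(self.X)
        keeps = [_keep_schedule(self.keep, self.n_components, Xs.shape[1])]
        design = np.array([[0.0, 1.0], [1.0, 0.0]])
        (W,), (T,), (P,), Q, ss_y = _block_nipals(
            [Xs], self.Y, self.n_components, keeps, design,
            self.max_iter, self.tol)
        return PLSDAResults(self, scaler, W, T, P, Q, ss_y)


@dataclass
class PLSDAResults:
    """Fitted PLS-DA: scores, sparse weights, loadings, class projections."""

    model: PLSDA
    scaler: _Scaler
    x_weights: np.ndarray   # p x A, sparse, unit norm per component
    x_scores: np.ndarray    # n x A, mutually orthogonal
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # c x A
    explained_y_ss: np.ndarray  # per-component explained class variance

    @property
    def classes_(self):
        return self.model.classes_

    def selected_features(self, component: int | None = None) -> list[str]:
        """Features with nonzero weight on one component (or any component)."""
        W = self.x_weights
        mask = (W[:, component] != 0) if component is not None else (W != 0).any(axis=1)
        return [f for f, m in zip(self.model.feature_names, mask) if m]

    def transform(self, X) -> np.ndarray:
        Xn, _, _ = _as_matrix(X) if not isinstance(X, np.ndarray) else (X, None, None)
        R = _rotation(self.x_weights, self.x_loadings)
        return self.scaler.apply(np.asarray(Xn, dtype=float)) @ R

    def vip(self) -> pd.Series:
        """Variable importance in projection; mean of VIP² is 1 by identity."""
        W = self.x_weights
        norms = np.linalg.norm(W, axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        Wn = W / norms
        ss = self.explained_y_ss
        denom = ss.sum() if ss.sum() > 0 else 1.0
        vip = np.sqrt(W.shape[0] * (Wn**2 @ ss) / denom)
        return pd.Series(vip, index=self.model.feature_names, name="VIP")

    def _centroids(self):
        scores = self.x_scores
        return {c: scores[np.asarray(self.model.y) == c].mean(axis=0)
                for c in self.classes_}

    def predict(self, X, distance: str = "centroid") -> np.ndarray:
        """Nearest-class-centroid prediction in score space.

        ``distance="centroid"`` is Euclidean; ``"mahalanobis"`` uses the
        pooled within-class score covariance.
        """
        scores = self.transform(X)
        cents = self._centroids()
        if distance == "mahalanobis":
            resid = np.vstack([self.x_scores[np.asarray(self.model.y) == c] - m
                               for c, m in cents.items()])
            cov = np.cov(resid, rowvar=False)
            cov = np.atleast_2d(cov) + 1e-10 * np.eye(scores.shape[1])
            icov = np.linalg.pinv(cov)
            dist = {c: np.einsum("ij,jk,ik->i", scores - m, icov, scores - m)
                    for c, m in cents.items()}
        elif distance == "centroid":
            dist = {c: ((scores - m)**2).sum(axis=1) for c, m in cents.items()}
        else:
            raise ValueError(f"unknown distance {distance!r}")
        mat = np.column_stack([dist[c] for c in self.classes_])
        return np.asarray(self.classes_)[mat.argmin(axis=1)]

    def summary(self) -> pd.DataFrame:
        rows = []
        for a in range(self.x_scores.shape[1]):
            rows.append({
                "component": a + 1,
                "explained_class_ss": self.explained_y_ss[a],
                "n_selected": int((self.x_weights[:, a] != 0).sum()),
            })
        return pd.DataFrame(rows)


def fit_plsda(X, y, n_components=None, keep_per_component=None,
              scale: bool = True) -> PLSDAResults:
    """Convenience wrapper: build and fit a :class:`PLSDA` model."""
    return PLSDA(X, y, n_components, keep_per_component, scale).fit()


def vip_scores(results: PLSDAResults) -> pd.Series:
    """Per-feature VIP of a fitted PLS-DA model."""
    return results.vip()


class BlockPLSDA:
    """Multi-block sparse PLS-DA (DIABLO-style sGCCA integration).

    Parameters
    ----------
    blocks : dict name -> (n_samples, n_features_b) DataFrame/array
        Feature blocks sharing the sample axis.
    y : class labels
    design_connectivity : float or (B x B) array
        Between-block connection weight(s); the class block is always fully
        connected with weight 1.  Default 1.0 (fully connected).
    keep : dict name -> keep spec, optional
        Per-block sparsity (int or per-component list); None keeps all.
    scale : bool or dict name -> bool
        Autoscaling per block (RADDi blocks conventionally unscaled).
    """

    def __init__(self, blocks: dict, y, n_components: int | None = None,
                 design_connectivity=1.0, keep: dict | None = None,
                 scale=True, max_iter: int = 500, tol: float = 1e-9):
        if not blocks:
            raise ValueError("need at least one block")
        self.block_names = list(blocks.keys())
        mats, feats = [], {}
        n_rows = None
        for name in self.block_names:
            M, fnames, _ = _as_matrix(blocks[name])
            if np.isnan(M).any():
                raise ValueError(f"block {name!r} contains missing values")
            if n_rows is None:
                n_rows = M.shape[0]
            elif M.shape[0] != n_rows:
                raise ValueError("blocks are non-conformable on the sample axis")
            mats.append(M)
            feats[name] = fnames
        self.mats = mats
        self.features = feats
        self.y = list(y)
        if len(self.y) != n_rows:
            raise ValueError("y length does not match the blocks")
        self.Y, self.classes_ = _one_hot(self.y)
        self.n_components = (n_components if n_components is not None
                             else len(self.classes_) - 1)
        B = len(mats)
        if np.isscalar(design_connectivity):
            C = np.full((B, B), float(design_connectivity))
            np.fill_diagonal(C, 0.0)
        else:
            C = np.asarray(design_connectivity, dtype=float)
        design = np.zeros((B, B + 1))
        design[:, :B] = C
        design[:, B] = 1.0
        self.design = design
        self.keep = keep or {}
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def _scale_flag(self, name: str) -> bool:
        return (self.scale.get(name, True) if isinstance(self.scale, dict)
                else bool(self.scale))

    def fit(self) -> "BlockPLSDAResults":
        scalers = {n: _Scaler.fit(M, self._scale_flag(n))
                   for n, M in zip(self.block_names, self.mats)}
        Xs = [scalers[n].apply(M) for n, M in zip(self.block_names, self.mats)]
        keeps = [_keep_schedule(self.keep.get(n), self.n_components, X.shape[1])
                 for n, X in zip(self.block_names, Xs)]
        W, T, P, Q, ss_y = _block_nipals(Xs, self.Y, self.n_components, keeps,
                                         self.design, self.max_iter, self.tol)
        return BlockPLSDAResults(
            self, scalers,
            {n: w for n, w in zip(self.block_names, W)},
            {n: t for n, t in zip(self.block_names, T)},
            {n: p for n, p in zip(self.block_names, P)},
            Q, ss_y)


@dataclass
class BlockPLSDAResults:
    """Fitted multi-block model: per-block scores/weights, consensus space."""

    model: BlockPLSDA
    scalers: dict
    block_weights: dict
    block_scores: dict
    block_loadings: dict
    y_loadings: np.ndarray
    explained_y_ss: np.ndarray

    @property
    def classes_(self):
        return self.model.classes_

    @property
    def consensus_scores(self) -> np.ndarray:
        return np.mean([self.block_scores[n] for n in self.model.block_names], axis=0)

    def score_correlations(self) -> pd.DataFrame:
        """Pearson correlation between block score vectors, per component."""
        rows = []
        names = self.model.block_names
        A = self.explained_y_ss.size
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                for a in range(A):
                    ti = self.block_scores[names[i]][:, a]
                    tj = self.block_scores[names[j]][:, a]
                    r = (np.corrcoef(ti, tj)[0, 1]
                         if ti.std() > 0 and tj.std() > 0 else np.nan)
                    rows.append({"block_a": names[i], "block_b": names[j],
                                 "component": a + 1, "correlation": r})
        return pd.DataFrame(rows)

    def pair_similarity(self, block_a: str, block_b: str) -> pd.DataFrame:
        """Latent-space (sGCCA-style) variable-pair correlations.

        The similarity of variable p (block a) and q (block b) is
        ``Σ_comp cor(x_p, t̄) · cor(x_q, t̄)`` over consensus components —
        the quantity networks between data levels are built from.
        """
        for name in (block_a, block_b):
            if name not in self.model.block_names:
                raise KeyError(f"unknown block {name!r}")
        t_bar = self.consensus_scores
        def cors(name):
            idx = self.model.block_names.index(name)
            X = self.scalers[name].apply(self.model.mats[idx])
            out = np.zeros((X.shape[1], t_bar.shape[1]))
            for a in range(t_bar.shape[1]):
                t = t_bar[:, a]
                sd = X.std(axis=0, ddof=1) * t.std(ddof=1)
                sd = np.where(sd > 0, sd, np.inf)
                out[:, a] = ((X - X.mean(axis=0)).T @ (t - t.mean())) / (
                    (len(t) - 1) * sd)
            return out
        ca, cb = cors(block_a), cors(block_b)
        sim = ca @ cb.T
        return pd.DataFrame(sim, index=self.model.features[block_a],
                            columns=self.model.features[block_b])

    def selected_features(self) -> dict[str, list[str]]:
        out = {}
        for name in self.model.block_names:
            mask = (self.block_weights[name] != 0).any(axis=1)
            out[name] = [f for f, m in zip(self.model.features[name], mask) if m]
        return out

    def _project(self, blocks: dict) -> np.ndarray:
        scores = []
        for name in self.model.block_names:
            M, _, _ = _as_matrix(blocks[name])
            R = _rotation(self.block_weights[name], self.block_loadings[name])
            scores.append(self.scalers[name].apply(M) @ R)
        return np.mean(scores, axis=0)

    def predict(self, blocks: dict, distance: str = "centroid") -> np.ndarray:
        """Nearest class centroid in consensus score space."""
        scores = self._project(blocks)
        train = self.consensus_scores
        y = np.asarray(self.model.y)
        cents = {c: train[y == c].mean(axis=0) for c in self.classes_}
        if distance == "mahalanobis":
            resid = np.vstack([train[y == c] - m for c, m in cents.items()])
            cov = np.atleast_2d(np.cov(resid, rowvar=False))
            icov = np.linalg.pinv(cov + 1e-10 * np.eye(cov.shape[0]))
            dist = {c: np.einsum("ij,jk,ik->i", scores - m, icov, scores - m)
                    for c, m in cents.items()}
        elif distance == "centroid":
            dist = {c: ((scores - m)**2).sum(axis=1) for c, m in cents.items()}
        else:
            raise ValueError(f"unknown distance {distance!r}")
        mat = np.column_stack([dist[c] for c in self.classes_])
        return np.asarray(self.classes_)[mat.argmin(axis=1)]


def fit_block_plsda(blocks: dict, y, n_components=None, design_connectivity=1.0,
                    keep: dict | None = None, scale=True) -> BlockPLSDAResults:
    """Convenience wrapper: build and fit a :class:`BlockPLSDA` model."""
    return BlockPLSDA(blocks, y, n_components, design_connectivity, keep,
                      scale).fit()


def _stratified_folds(y, folds: int, rng: np.random.Generator):
    """Stratified fold assignment; every class appears in every training split."""
    y = np.asarray(y)
    assignment = np.zeros(len(y), dtype=int)
    for c in pd.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


@dataclass
class ConsensusModel:
    """Tuned multi-block consensus: selected classifiers and their CV error."""

    results: BlockPLSDAResults
    keep: dict
    n_components: int
    folds: int
    cv_error: float
    cv_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def selected(self) -> dict[str, list[str]]:
        return self.results.selected_features()

    @property
    def n_classifiers(self) -> int:
        return sum(len(v) for v in self.selected.values())

    def summary(self) -> str:
        parts = [f"Consensus model: {self.n_classifiers} classifiers, "
                 f"{self.n_components} component(s), "
                 f"{self.folds}-fold CV error {self.cv_error:.3f}"]
        for name, feats in self.selected.items():
            parts.append(f"  block {name}: {len(feats)} selected")
        return "\n".join(parts)


def cross_val_error(blocks: dict, y, keep: dict | None, n_components: int,
                    folds: int = 5, distance: str = "centroid", seed: int = 0,
                    design_connectivity=1.0, scale=True,
                    max_refold: int = 10) -> float:
    """Overall misclassification rate by stratified k-fold cross-validation."""
    y_arr = np.asarray(list(y))
    rng = np.random.default_rng(seed)
    mats = {n: _as_matrix(b)[0] for n, b in blocks.items()}
    for attempt in range(max_refold):
        assignment = _stratified_folds(y_arr, folds, rng)
        ok = all(len(np.unique(y_arr[assignment != f])) == len(np.unique(y_arr))
                 for f in range(folds))
        if ok:
            break
    else:
        raise ValueError("could not stratify folds with every class in training")
    errors = 0
    for f in range(folds):
        train, test = assignment != f, assignment == f
        if not test.any():
            continue
        fit = BlockPLSDA({n: M[train] for n, M in mats.items()}, y_arr[train],
                         n_components=n_components, keep=keep, scale=scale,
                         design_connectivity=design_connectivity).fit()
        pred = fit.predict({n: M[test] for n, M in mats.items()}, distance)
        errors += int((pred != y_arr[test]).sum())
    return errors / len(y_arr)


def tune_cv(blocks: dict, y, candidate_keeps: list, n_components_grid=None,
            folds: int = 5, distance: str = "centroid", seed: int = 0,
            design_connectivity=1.0, scale=True) -> ConsensusModel:
    """Grid-search sparsity and component count by stratified k-fold CV.

    ``candidate_keeps`` is a list of per-block keep dicts (or ``None`` for a
    dense model).  Returns the argmin consensus model refitted on all data,
    with its feature list and CV error; ties resolve to the earliest grid
    cell, so the same seed yields the same selected model.
    """
    classes = pd.unique(pd.Series(list(y)))
    if n_components_grid is None:
        n_components_grid = [len(classes) - 1]
    rows = []
    best = None
    for ncomp in n_components_grid:
        for ki, keep in enumerate(candidate_keeps):
            err = cross_val_error(blocks, y, keep, ncomp, folds, distance,
                                  seed, design_connectivity, scale)
            rows.append({"n_components": ncomp, "keep_index": ki, "cv_error": err})
            if best is None or err < best[0]:
                best = (err, ncomp, keep)
    err, ncomp, keep = best
    final = BlockPLSDA(blocks, y, n_components=ncomp, keep=keep, scale=scale,
                       design_connectivity=design_connectivity).fit()
    return ConsensusModel(final, keep or {}, ncomp, folds, err, pd.DataFrame(rows))
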