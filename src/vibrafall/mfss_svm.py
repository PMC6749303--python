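"""Multi-feature semi-supervised SVM (tri-training + majority vote).

The detector trains one soft-margin RBF SVM per feature view (peak,
energy, sensor correlation).  With only a fraction of the training events
labelled, the three view classifiers are co-trained:

1. fit each view's SVM on the labelled rows (pseudo-labelled rows, once
   they exist, enter the fit with a reduced penalty ``C* < C``, realised
   as a per-sample weight ``C*/C``);
2. for each view, consider the unlabelled rows inside its margin band
   (decision value ``0 < |y| <= 1``) — the rows that can still move the
   hyperplane, with those nearest ``|y| = 1`` the most reliably labelled;
3. of those candidates, keep the ones on which the *other two* views
   agree, pseudo-label them with the agreed class, rank by closeness to
   the margin (``||y| - 1||`` ascending) and add the top fraction;
4. any previously pseudo-labelled row whose ensemble label flips is
   returned to the unlabelled pool;
5. repeat until nothing is added or removed, or ``max_iter`` is reached.

Prediction is the majority vote of the three view classifiers (three
binary voters cannot tie).  Labels are ``+1`` (fall), ``-1`` (non-fall);
``0`` marks unlabelled rows in ``fit``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted

from .features import VIEW_NAMES, FeatureView, extract_views, stack_views
from .signal_core import EventDataset

__all__ = [
    "MFSSSVMClassifier",
    "fit_base",
    "select_semi_labels",
    "fit_mfss",
    "predict",
    "labeling_rate_experiment",
    "infer_n_sensors",
    "save_model",
    "load_model",
]


def infer_n_sensors(n_features: int) -> int:
    """Invert ``d = n + n + n(n-1)/2`` to recover the sensor count."""
    # 2n + n(n-1)/2 = d  =>  n^2 + 3n - 2d = 0
    n = (-3 + math.isqrt(9 + 8 * n_features)) // 2
    if n < 2 or 2 * n + n * (n - 1) // 2 != n_features:
        raise ValueError(
            f"feature width {n_features} does not match any sensor count "
            "(expected n + n + n(n-1)/2 stacked view columns)"
        )
    return n


def _view_slices(n_sensors: int) -> list[slice]:
    n_corr = n_sensors * (n_sensors - 1) // 2
    return [
        slice(0, n_sensors),
        slice(n_sensors, 2 * n_sensors),
        slice(2 * n_sensors, 2 * n_sensors + n_corr),
    ]


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise distance: gamma = 1/(2 med^2)."""
    d = pairwise_distances(X)
    med = np.median(d[np.triu_indices_from(d, k=1)]) if X.shape[0] > 1 else 0.0
    if not np.isfinite(med) or med <= 0:
        return 1.0 / X.shape[1]
    return 1.0 / (2.0 * med ** 2)


class MFSSSVMClassifier(ClassifierMixin, BaseEstimator):
    """Multi-view semi-supervised fall detector (tri-training ensemble).

    Parameters
    ----------
    C : float, default=1.0
        Penalty for labelled samples.
    c_star : float or None, default=None
        Penalty for pseudo-labelled samples; ``0.5 * C`` when None.
    gamma : float or "median", default="median"
        RBF width; ``"median"`` uses the median-pairwise-distance heuristic
        on the (standardised) labelled rows of each view.
    max_iter : int, default=20
        Tri-training iterations; ``0`` degenerates to the purely supervised
        three-view vote (no pseudo-labelling).
    add_cap : float, default=0.1
        Per-view, per-iteration cap on additions, as a fraction of the
        current unlabelled pool.
    margin_band : float, default=1.0
        Candidate band ``0 < |decision value| <= margin_band``.
    error_gate : bool, default=True
        Classical tri-training error control: a view accepts new
        pseudo-labels only while its peers' joint labelling error
        (estimated on the labelled rows where the peers agree) is below
        the view's own labelled-set error, so pseudo-label noise cannot
        exceed the error it could correct.
    strict_peer_check : bool, default=True
        Require both peer views to place a candidate outside their own
        margin bands (confident agreement) before its pseudo-label is
        accepted; without it, peers endorse labels in regions where they
        are themselves uncertain.
    validate : bool, default=True
        Validated acceptance: keep the co-trained ensemble only if its
        stratified-CV vote accuracy on the labelled rows is at least the
        supervised ensemble's; otherwise revert (``stop_reason_ ==
        "reverted"``).
    standardize : bool, default=True
        Z-score each view using the labelled training rows only.
    n_sensors : int or None, default=None
        Sensor count behind the stacked feature matrix; inferred from the
        feature width when None.

    Attributes
    ----------
    classifiers_ : list of three fitted SVC (peak, energy, corr views).
    scalers_ : list of three fitted StandardScaler (or None).
    history_ : list of per-iteration dicts (additions, removals) plus
        stopping reason; conservation holds: total added - total removed
        equals the final pseudo-label count.
    n_iter_ : int
    stop_reason_ : str
    semi_indices_ : ndarray of row indices that ended up pseudo-labelled.
    semi_labels_ : ndarray of their pseudo-labels.
    """

    def __init__(
        self,
        C: float = 1.0,
        c_star: float | None = None,
        gamma: float | str = "median",
        max_iter: int = 20,
        add_cap: float = 0.1,
        margin_band: float = 1.0,
        error_gate: bool = True,
        strict_peer_check: bool = True,
        validate: bool = True,
        standardize: bool = True,
        n_sensors: int | None = None,
    ):
        self.C = C
        self.c_star = c_star
        self.gamma = gamma
        self.max_iter = max_iter
        self.add_cap = add_cap
        self.margin_band = margin_band
        self.error_gate = error_gate
        self.strict_peer_check = strict_peer_check
        self.validate = validate
        self.standardize = standardize
        self.n_sensors = n_sensors

    # -- helpers ------------------------------------------------------------

    def _split(self, X: np.ndarray) -> list[np.ndarray]:
        return [X[:, s] for s in self.view_slices_]

    def _fit_view(self, Z: np.ndarray, y: np.ndarray, w: np.ndarray, gamma: float) -> SVC:
        svc = SVC(C=self.C, kernel="rbf", gamma=gamma)
        svc.fit(Z, y, sample_weight=w)
        return svc

    def _cv_predictions(self, Z, y, lab_idx, n_splits: int = 5):
        """Per-view cross-validated predictions on the labelled rows."""
        from sklearn.model_selection import StratifiedKFold

        y_lab = y[lab_idx]
        n_splits = min(n_splits, int(np.min(np.bincount((y_lab + 1) // 2))))
        preds = [np.zeros(lab_idx.size, dtype=int) for _ in range(3)]
        if n_splits < 2:
            # too few labelled rows of one class for CV; fall back to
            # training-set predictions (optimistic, but degenerate case)
            for j in range(3):
                svc = self._fit_view(Z[j][lab_idx], y_lab,
                                     np.ones(lab_idx.size), self.gammas_[j])
                preds[j] = np.sign(svc.decision_function(Z[j][lab_idx])).astype(int)
            return preds
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=0)
        for tr, te in skf.split(np.zeros(lab_idx.size), y_lab):
            for j in range(3):
                svc = self._fit_view(Z[j][lab_idx[tr]], y_lab[tr],
                                     np.ones(tr.size), self.gammas_[j])
                preds[j][te] = np.sign(
                    svc.decision_function(Z[j][lab_idx[te]])
                ).astype(int)
        return preds

    def _cv_accepts(self, Z, y, lab_idx, semi, w_semi, n_splits: int = 5) -> bool:
        """Compare co-trained vs supervised vote by CV over labelled rows."""
        from sklearn.model_selection import StratifiedKFold

        y_lab = y[lab_idx]
        n_splits = min(n_splits, int(np.min(np.bincount((y_lab + 1) // 2))))
        if n_splits < 2:
            return True
        votes_semi = np.zeros(lab_idx.size)
        votes_sup = np.zeros(lab_idx.size)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=1)
        for tr, te in skf.split(np.zeros(lab_idx.size), y_lab):
            for j in range(3):
                semi_idx = np.fromiter(semi[j].keys(), dtype=int, count=len(semi[j]))
                rows = np.concatenate([lab_idx[tr], semi_idx]).astype(int)
                yy = np.concatenate(
                    [y_lab[tr], np.array([semi[j][i] for i in semi_idx], dtype=int)]
                )
                ww = np.concatenate([np.ones(tr.size), np.full(semi_idx.size, w_semi)])
                svc = self._fit_view(Z[j][rows], yy, ww, self.gammas_[j])
                votes_semi[te] += np.sign(svc.decision_function(Z[j][lab_idx[te]]))
                svc0 = self._fit_view(Z[j][lab_idx[tr]], y_lab[tr],
                                      np.ones(tr.size), self.gammas_[j])
                votes_sup[te] += np.sign(svc0.decision_function(Z[j][lab_idx[te]]))
        ok_semi = np.sign(votes_semi) == y_lab
        ok_sup = np.sign(votes_sup) == y_lab
        # paired sign-test criterion on the discordant rows: accept only if
        # the co-trained ensemble's net wins exceed two standard deviations
        # of the discordance (chance-level improvements are rejected)
        wins = int(np.sum(ok_semi & ~ok_sup))
        losses = int(np.sum(~ok_semi & ok_sup))
        discordant = wins + losses
        if discordant == 0:
            return False
        return (wins - losses) > 2.0 * np.sqrt(discordant)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        """Fit on a stacked view matrix.

        ``y`` entries: ``+1`` fall, ``-1`` non-fall, ``0`` unlabelled.
        """
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.all(np.isin(y, (-1, 0, 1))):
            raise ValueError("labels must be in {+1, -1, 0 (unlabelled)}")
        if self.C <= 0 or (self.c_star is not None and self.c_star <= 0):
            raise ValueError("penalty parameters must be positive")
        if not (0 < self.add_cap <= 1):
            raise ValueError("add_cap must lie in (0, 1]")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")

        n_sensors = self.n_sensors or infer_n_sensors(X.shape[1])
        self.n_sensors_ = n_sensors
        self.view_slices_ = _view_slices(n_sensors)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([-1, 1])

        labeled = y != 0
        counts = {c: int(np.sum(y[labeled] == c)) for c in (-1, 1)}
        if counts[-1] == 0 or counts[1] == 0:
            raise ValueError(
                f"both classes required among labelled rows; got {counts[1]} "
                f"fall (+1) and {counts[-1]} non-fall (-1)"
            )

        views = self._split(X)
        # standardisation statistics come from the labelled rows only so
        # that unlabelled/test rows cannot leak into the transform
        self.scalers_ = []
        Z = []
        for V in views:
            if self.standardize:
                sc = StandardScaler().fit(V[labeled])
                self.scalers_.append(sc)
                Z.append(sc.transform(V))
            else:
                self.scalers_.append(None)
                Z.append(V)

        self.gammas_ = [
            _median_heuristic_gamma(Zj[labeled]) if self.gamma == "median" else float(self.gamma)
            for Zj in Z
        ]

        c_star = 0.5 * self.C if self.c_star is None else self.c_star
        w_semi = c_star / self.C

        lab_idx = np.flatnonzero(labeled)
        unlab_idx = np.flatnonzero(~labeled)
        # canonical tri-training: each view keeps its own pseudo-labelled
        # set, provided by the agreement of the other two views; a view
        # never trains on labels derived from its own predictions, which
        # keeps the three members diverse and prevents self-reinforcement
        pools: list[set[int]] = [set(unlab_idx) for _ in range(3)]
        semi: list[dict[int, int]] = [{}, {}, {}]
        history: list[dict] = []

        def fit_view(j: int) -> SVC:
            semi_idx = np.fromiter(semi[j].keys(), dtype=int, count=len(semi[j]))
            rows = np.concatenate([lab_idx, semi_idx]).astype(int)
            yy = np.concatenate(
                [y[lab_idx], np.array([semi[j][i] for i in semi_idx], dtype=int)]
            )
            ww = np.concatenate([np.ones(lab_idx.size), np.full(semi_idx.size, w_semi)])
            return self._fit_view(Z[j][rows], yy, ww, self.gammas_[j])

        clfs = [fit_view(j) for j in range(3)]

        # error-rate gate: view j accepts pseudo-labels only if the joint
        # labelling error of its two peers (on rows where they agree) is
        # below the view's own error — otherwise pseudo-label noise would
        # exceed the error it could correct.  Both errors are estimated by
        # stratified cross-validation on the labelled rows; training-set
        # errors of an RBF-SVM are far too optimistic to compare.
        gate = [True, True, True]
        if self.error_gate and self.max_iter > 0:
            cv_pred = self._cv_predictions(Z, y, lab_idx)
            own_err_cv = [float(np.mean(cv_pred[j] != y[lab_idx])) for j in range(3)]
            for j in range(3):
                p1, p2 = [k for k in range(3) if k != j]
                agree = cv_pred[p1] == cv_pred[p2]
                if agree.any():
                    peer_err = float(np.mean(cv_pred[p1][agree] != y[lab_idx][agree]))
                else:
                    peer_err = 0.5
                gate[j] = peer_err < max(own_err_cv[j], 1e-12)
            self.gate_ = {name: bool(g) for name, g in zip(VIEW_NAMES, gate)}
        else:
            self.gate_ = {name: True for name in VIEW_NAMES}

        # pseudo-label additions keep the labelled class ratio so that the
        # majority class cannot swamp the minority through self-labelling
        frac_pos = float(np.mean(y[lab_idx] == 1))

        stop_reason = "supervised" if self.max_iter == 0 else "max_iter"
        for it in range(self.max_iter):
            added = {name: 0 for name in VIEW_NAMES}
            removed_n = 0
            for j, name in enumerate(VIEW_NAMES):
                p1, p2 = [k for k in range(3) if k != j]
                gate_open = gate[j]
                # flip removal: pseudo-labels whose peer endorsement changed
                if semi[j]:
                    idx = np.fromiter(semi[j].keys(), dtype=int, count=len(semi[j]))
                    q1 = np.sign(clfs[p1].decision_function(Z[p1][idx])).astype(int)
                    q2 = np.sign(clfs[p2].decision_function(Z[p2][idx])).astype(int)
                    for i, a, b in zip(idx, q1, q2):
                        if a != b or a != semi[j][i]:
                            del semi[j][int(i)]
                            pools[j].add(int(i))
                            removed_n += 1
                # margin-band candidates of this view, labelled by its peers
                if pools[j] and gate_open:
                    pool_arr = np.asarray(sorted(pools[j]), dtype=int)
                    n_take = int(np.ceil(self.add_cap * pool_arr.size))
                    dec_j = clfs[j].decision_function(Z[j][pool_arr])
                    d1 = clfs[p1].decision_function(Z[p1][pool_arr])
                    d2 = clfs[p2].decision_function(Z[p2][pool_arr])
                    sel, lab = select_semi_labels(
                        dec_j,
                        np.sign(d1).astype(int),
                        np.sign(d2).astype(int),
                        cap_count=pool_arr.size,
                        margin_band=self.margin_band,
                        peer_decisions=(d1, d2) if self.strict_peer_check else None,
                    )
                    # keep additions at the labelled class ratio, scaled to
                    # the scarcer class (the transductive-SVM balance
                    # constraint): one-sided additions would otherwise walk
                    # the boundary into the minority class
                    target = {
                        1: max(frac_pos * n_take, 1e-12),
                        -1: max((1 - frac_pos) * n_take, 1e-12),
                    }
                    avail = {c: [s for s, l in zip(sel, lab) if l == c] for c in (1, -1)}
                    scale = min(
                        1.0, len(avail[1]) / target[1], len(avail[-1]) / target[-1]
                    )
                    for c in (1, -1):
                        for s_loc in avail[c][: int(round(scale * target[c]))]:
                            row = int(pool_arr[s_loc])
                            semi[j][row] = int(c)
                            pools[j].discard(row)
                            added[name] += 1

            history.append({
                "iteration": it + 1,
                "added": added,
                "added_total": int(sum(added.values())),
                "removed": removed_n,
                "semi_count": sum(len(s) for s in semi),
            })
            clfs = [fit_view(j) for j in range(3)]
            if sum(added.values()) == 0 and removed_n == 0:
                stop_reason = "converged"
                break

        # validated acceptance: keep the co-trained ensemble only if it is
        # at least as accurate as the supervised ensemble under stratified
        # cross-validation on the labelled rows (pseudo-labels held fixed,
        # per-fold refits) — co-training that cannot demonstrate a benefit
        # on held-out labelled data is discarded
        if self.validate and any(len(s) for s in semi):
            if not self._cv_accepts(Z, y, lab_idx, semi, w_semi):
                for j in range(3):
                    semi[j].clear()
                clfs = [fit_view(j) for j in range(3)]
                stop_reason = "reverted"

        self.classifiers_ = clfs
        self.history_ = history
        self.n_iter_ = len(history)
        self.stop_reason_ = stop_reason
        all_semi: dict[int, int] = {}
        for s in semi:
            all_semi.update(s)
        self.semi_indices_ = np.array(sorted(all_semi), dtype=int)
        self.semi_labels_ = np.array([all_semi[i] for i in self.semi_indices_], dtype=int)
        self.semi_per_view_ = [dict(s) for s in semi]
        return self

    def _transform_views(self, X) -> list[np.ndarray]:
        check_is_fitted(self, "classifiers_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} does not match training width "
                f"{self.n_features_in_}"
            )
        views = self._split(X)
        return [
            sc.transform(V) if sc is not None else V
            for sc, V in zip(self.scalers_, views)
        ]

    def decision_function(self, X) -> np.ndarray:
        """Sum of the three per-view signed votes (in {-3, -1, +1, +3})."""
        return self.predict_views(X).sum(axis=1).astype(float)

    def predict_views(self, X) -> np.ndarray:
        """Per-view votes, shape (n_events, 3), columns (peak, energy, corr)."""
        Z = self._transform_views(X)
        return np.column_stack([
            np.sign(self.classifiers_[j].decision_function(Z[j])).astype(int)
            for j in range(3)
        ])

    def predict(self, X) -> np.ndarray:
        """Majority vote of the three view classifiers, in {+1, -1}."""
        return np.sign(self.predict_views(X).sum(axis=1)).astype(int)


# ---------------------------------------------------------------------------
# Module-level operations (thin wrappers over the estimator)
# ---------------------------------------------------------------------------


def fit_base(
    view_matrix: np.ndarray,
    labels: Sequence[int],
    C: float = 1.0,
    gamma: float | str = "median",
    standardize: bool = True,
):
    """Fit one supervised RBF base classifier for a single view.

    Returns an object exposing ``decision_function`` and ``predict`` over
    raw (unstandardised) view rows.
    """
    V = check_array(np.asarray(view_matrix, dtype=float))
    y = np.asarray(labels)
    counts = {c: int(np.sum(y == c)) for c in (-1, 1)}
    if counts[-1] == 0 or counts[1] == 0:
        raise ValueError(
            f"both classes required: got {counts[1]} fall (+1) and "
            f"{counts[-1]} non-fall (-1) labelled rows"
        )
    sc = StandardScaler().fit(V) if standardize else None
    Z = sc.transform(V) if sc is not None else V
    g = _median_heuristic_gamma(Z) if gamma == "median" else float(gamma)
    svc = SVC(C=C, kernel="rbf", gamma=g).fit(Z, y)

    class _Base:
        scaler = sc
        svc_ = svc
        gamma_ = g

        def decision_function(self, Xnew):
            Xnew = np.asarray(Xnew, dtype=float)
            return svc.decision_function(sc.transform(Xnew) if sc is not None else Xnew)

        def predict(self, Xnew):
            return np.sign(self.decision_function(Xnew)).astype(int)

    return _Base()


def select_semi_labels(
    own_decision: np.ndarray,
    peer_pred_1: np.ndarray,
    peer_pred_2: np.ndarray,
    cap_count: int | None = None,
    cap: float | None = None,
    margin_band: float = 1.0,
    peer_decisions: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Margin-proximity candidate selection with peer agreement.

    Candidates are unlabelled rows with ``0 < |y| <= margin_band`` under the
    view's own decision values on which the two peer views agree; they are
    ranked by ``||y| - 1||`` ascending (closest to the margin first) and the
    top ``cap_count`` (or ``ceil(cap * n_rows)``) are returned as
    ``(indices, pseudo_labels)``.
    """
    d = np.asarray(own_decision, dtype=float)
    p1 = np.asarray(peer_pred_1)
    p2 = np.asarray(peer_pred_2)
    if cap_count is None:
        if cap is None:
            raise ValueError("provide cap_count or cap")
        cap_count = int(np.ceil(cap * d.size))
    mask = (np.abs(d) > 0) & (np.abs(d) <= margin_band) & (p1 == p2) & (p1 != 0)
    if peer_decisions is not None:
        q1, q2 = peer_decisions
        mask &= (np.abs(q1) > margin_band) & (np.abs(q2) > margin_band)
    cand = np.flatnonzero(mask)
    if cand.size == 0 or cap_count <= 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(np.abs(np.abs(d[cand]) - 1.0), kind="stable")
    sel = cand[order[:cap_count]]
    return sel, p1[sel].astype(int)


def fit_mfss(
    views: tuple[FeatureView, FeatureView, FeatureView] | Sequence[np.ndarray],
    labels: Sequence[int],
    **params,
) -> MFSSSVMClassifier:
    """Fit the tri-training ensemble from three view matrices.

    ``labels`` uses ``+1`` / ``-1`` / ``0`` (unlabelled).  Keyword
    parameters are forwarded to :class:`MFSSSVMClassifier`.
    """
    if views and isinstance(views[0], FeatureView):
        X = stack_views(tuple(views))
    else:
        X = np.hstack([np.asarray(V, dtype=float) for V in views])
    return MFSSSVMClassifier(**params).fit(X, np.asarray(labels))


def predict(ens: MFSSSVMClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels plus the per-view votes for diagnostics."""
    votes = ens.predict_views(X)
    return np.sign(votes.sum(axis=1)).astype(int), votes


# ---------------------------------------------------------------------------
# Labeling-rate experiment harness
# ---------------------------------------------------------------------------


def _stratified_label_mask(
    y: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of rows kept labelled, stratified per class."""
    mask = np.zeros(y.size, dtype=bool)
    for c in (-1, 1):
        idx = np.flatnonzero(y == c)
        n_keep = max(1, int(round(rate * idx.size)))
        if idx.size == 0:
            raise ValueError(
                f"class {c} absent from the training rows; cannot stratify"
            )
        keep = rng.choice(idx, size=min(n_keep, idx.size), replace=False)
        mask[keep] = True
    return mask


def labeling_rate_experiment(
    ds: EventDataset,
    rates: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    split: float = 0.7,
    n_repeats: int = 3,
    seed: int | None = None,
    **params,
):
    """Initial vs final accuracy of the detector across labelling rates.

    For each rate and repeat: stratified train/test split (train fraction
    ``split``), stratified labelled subset at the rate, then

    * *initial accuracy* — the supervised three-view majority vote fitted
      on the labelled rows only (``max_iter=0``),
    * *final accuracy* — the full tri-training ensemble,

    both scored on the held-out test events, plus sensitivity and
    specificity of the final model.  Results are averaged over repeats.

    Returns a pandas DataFrame with one row per rate and columns
    ``(rate, initial_accuracy, final_accuracy, relative_gain,
    sensitivity, specificity)``; accuracies are percentages and
    ``relative_gain = 100 (final - initial) / initial``.
    """
    import pandas as pd

    from .evaluation import evaluate, relative_change

    rates = list(rates)
    if any(not (0 < r <= 1) for r in rates):
        raise ValueError("labelling rates must lie in (0, 1]")
    if not (0 < split < 1):
        raise ValueError("train split must lie in (0, 1)")
    views = extract_views(ds)
    X = stack_views(views)
    y = ds.binary_labels()
    if np.any(y == 0):
        raise ValueError("the experiment needs fully labelled ground truth")
    activities = np.asarray(ds.labels())
    rng = np.random.default_rng(seed)

    rows = []
    for rate in rates:
        acc_i, acc_f, se, sp = [], [], [], []
        for _ in range(n_repeats):
            rs = int(rng.integers(0, 2 ** 31 - 1))
            idx_train, idx_test = train_test_split(
                np.arange(y.size), train_size=split, stratify=y, random_state=rs
            )
            y_train = y[idx_train].copy()
            mask = _stratified_label_mask(y_train, rate, np.random.default_rng(rs))
            y_semi = np.where(mask, y_train, 0)

            base = MFSSSVMClassifier(**params)
            initial = clone(base).set_params(max_iter=0).fit(X[idx_train], y_semi)
            final = base.fit(X[idx_train], y_semi)

            pred_i = initial.predict(X[idx_test])
            pred_f = final.predict(X[idx_test])
            rep_i = evaluate(pred_i, y[idx_test], activities[idx_test])
            rep_f = evaluate(pred_f, y[idx_test], activities[idx_test])
            acc_i.append(rep_i.accuracy)
            acc_f.append(rep_f.accuracy)
            se.append(rep_f.sensitivity)
            sp.append(rep_f.specificity)
        mi, mf = float(np.mean(acc_i)), float(np.mean(acc_f))
        rows.append({
            "rate": rate,
            "initial_accuracy": mi,
            "final_accuracy": mf,
            "relative_gain": relative_change(mf, mi),
            "sensitivity": float(np.mean([s for s in se if s is not None])),
            "specificity": float(np.mean([s for s in sp if s is not None])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def save_model(ens: MFSSSVMClassifier, path) -> None:
    """Persist a fitted ensemble (classifiers, scalers, config, history)."""
    import joblib

    check_is_fitted(ens, "classifiers_")
    joblib.dump({"schema_version": _SCHEMA_VERSION, "model": ens}, path)


def load_model(path) -> MFSSSVMClassifier:
    import joblib

    payload = joblib.load(path)
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema {payload.get('schema_version')!r}"
        )
    return payload["model"]
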