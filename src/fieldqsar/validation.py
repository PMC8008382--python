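"""Model validation: cross-validation, Y-scrambling, external prediction.

Internal robustness is measured by leave-one-out (LOO) or leave-some-out
(LSO) cross-validation, producing q² and SDEP.  Chance correlation is
probed by Y-scrambling: the response vector is randomly permuted and the
model rederived; r²_YS and q²_YS should fall well below the original
model's values.  External predictive ability is measured on a held-out
test set via SDEP_ext and r²_pred.

q² uses the leakage-free convention: each fold's model (including
centering and any block re-scaling) is fit on the retained rows only, and
the q² denominator accumulates squared deviations of the held-out
responses from the *training-fold* mean.  The alternative global-mean
denominator is available via ``q2_denominator="global"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .chem_data import QsarDataset
from .fields import FieldBlock, GridSpec, Probe, assemble_descriptor_matrix, compute_mif
from .pls import PlsModel, fit_pls, predict, r_squared, sd_error

__all__ = [
    "CvScheme",
    "ValidationReport",
    "ScramblingReport",
    "cross_validate",
    "select_components",
    "y_scramble",
    "external_predict",
    "block_scales",
    "make_block_refit",
]

DEFAULT_LSO_GROUPS = 5
DEFAULT_LSO_REPEATS = 20
DEFAULT_N_SCRAMBLES = 20


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation scheme: LOO, or LSO with seeded random groups."""

    kind: Literal["LOO", "LSO"] = "LOO"
    n_groups: int = DEFAULT_LSO_GROUPS
    n_repeats: int = DEFAULT_LSO_REPEATS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("LOO", "LSO"):
            raise ValueError("kind must be LOO or LSO")
        if self.kind == "LSO" and self.n_groups < 2:
            raise ValueError("LSO needs at least 2 groups")


@dataclass
class ValidationReport:
    q2: float
    sdep: float
    per_fold_predictions: dict[str, float]
    scheme: CvScheme
    n_components: int
    q2_per_repeat: list[float] = field(default_factory=list)


@dataclass
class ScramblingReport:
    n_scrambles: int
    seed: int
    r2_ys: list[float]
    q2_ys: list[float]
    original_r2: float
    original_q2: float


def _partitions(n: int, scheme: CvScheme):
    """Yield (repeat, list-of-heldout-index-arrays)."""
    if scheme.kind == "LOO":
        yield 0, [np.array([i]) for i in range(n)]
        return
    if scheme.n_groups > n:
        raise ValueError("LSO n_groups exceeds the number of rows")
    for rep in range(scheme.n_repeats):
        rng = np.random.default_rng((scheme.seed, rep))
        perm = rng.permutation(n)
        groups = [np.sort(g) for g in np.array_split(perm, scheme.n_groups)]
        # fold order fixed by first held-out index so that LSO with
        # n_groups = n accumulates identically to LOO
        yield rep, sorted(groups, key=lambda g: int(g[0]))


def _default_fitter(
    X: np.ndarray, y: np.ndarray, n_components: int
) -> tuple[PlsModel, Callable[[np.ndarray], np.ndarray]]:
    m = fit_pls(X, y, n_components)
    return m, lambda Xn: predict(m, Xn)


def block_scales(X: np.ndarray, provenance: Sequence[tuple[str, int]]) -> np.ndarray:
    """Per-column block-scaling divisors recomputed from the given rows.

    Columns of each field block are divided by the square root of the
    block's total column variance, equalizing the fields' contributions.
    """
    prov_types = np.array([t for t, _ in provenance])
    scales = np.ones(X.shape[1])
    for ft in dict.fromkeys(prov_types):
        sel = prov_types == ft
        total_var = float(X[:, sel].var(axis=0, ddof=1).sum())
        if total_var > 0:
            scales[sel] = np.sqrt(total_var)
    return scales


def make_block_refit(provenance: Sequence[tuple[str, int]]) -> Callable:
    """Refit closure that redoes block scaling inside every CV fold.

    Passing this to :func:`cross_validate` keeps the scaling leakage-free:
    the divisors are computed from the fold's training rows only.
    """
    prov = list(provenance)

    def refit(X: np.ndarray, y: np.ndarray, n_components: int):
        m = fit_pls(X, y, n_components, x_scale=block_scales(X, prov),
                    column_provenance=prov)
        return m, lambda Xn: predict(m, Xn)

    return refit


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scheme: CvScheme,
    mol_ids: Sequence[str] | None = None,
    refit: Callable | None = None,
    q2_denominator: Literal["train_fold", "global"] = "train_fold",
) -> ValidationReport:
    """Cross-validated q² and SDEP by full refits inside every fold.

    ``refit(X_train, y_train, n_components)`` may be supplied to rebuild
    the whole preprocessing (e.g. per-fold block rescaling); it must return
    ``(model, predict_fn)``.  By default a plain PLS refit (which
    re-centers within the fold) is used.  LSO averages q² and SDEP over
    ``scheme.n_repeats`` seeded partitions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("cross-validation needs at least 3 rows")
    refit = refit or _default_fitter
    ids = list(mol_ids) if mol_ids is not None else [str(i) for i in range(n)]

    q2s, sdeps = [], []
    predictions: dict[str, float] = {}
    for rep, folds in _partitions(n, scheme):
        press = 0.0
        denom = 0.0
        for heldout in folds:
            train = np.setdiff1d(np.arange(n), heldout)
            if len(train) < 2:
                raise ValueError("a fold left fewer than 2 training rows")
            ncomp = min(n_components, len(train) - 1)
            if ncomp < n_components:
                warnings.warn(
                    f"n_components reduced to {ncomp} in a fold with "
                    f"{len(train)} rows",
                    stacklevel=2,
                )
            model, predict_fn = refit(X[train], y[train], ncomp)
            y_hat = np.asarray(predict_fn(X[heldout])).ravel()
            press += float(np.sum((y[heldout] - y_hat) ** 2))
            ref_mean = y[train].mean() if q2_denominator == "train_fold" else y.mean()
            denom += float(np.sum((y[heldout] - ref_mean) ** 2))
            if rep == 0:
                for k, idx in enumerate(heldout):
                    predictions[ids[idx]] = float(y_hat[k])
        q2s.append(1.0 - press / denom)
        sdeps.append(float(np.sqrt(press / n)))

    # identical repeats (e.g. LSO with n_groups = n, which is LOO) must
    # average to exactly their common value
    return ValidationReport(
        q2=q2s[0] if len(set(q2s)) == 1 else float(np.mean(q2s)),
        sdep=sdeps[0] if len(set(sdeps)) == 1 else float(np.mean(sdeps)),
        per_fold_predictions=predictions,
        scheme=scheme,
        n_components=n_components,
        q2_per_repeat=[float(v) for v in q2s],
    )


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    scheme: CvScheme,
    refit: Callable | None = None,
) -> tuple[int, list[float]]:
    """Optimal number of PLS components by cross-validated q².

    Returns ``(onpc, q2_profile)``; ties go to the fewest components.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    hard_max = min(len(y) - 1, np.asarray(X).shape[1])
    profile = []
    for a in range(1, min(max_components, hard_max) + 1):
        rep = cross_validate(X, y, a, scheme, refit=refit)
        profile.append(rep.q2)
    onpc = int(np.argmax(profile)) + 1  # argmax returns the first maximum
    return onpc, profile


def y_scramble(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_scrambles: int,
    seed: int,
    scheme: CvScheme,
    refit: Callable | None = None,
) -> ScramblingReport:
    """Chance-correlation test by seeded response permutation.

    Each scramble permutes y (Fisher-Yates via the generator's
    ``permutation``; the identity permutation is rejected and redrawn),
    refits the full model for r²_YS and cross-validates for q²_YS.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 4:
        raise ValueError("Y-scrambling needs at least 4 rows")
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    refit = refit or _default_fitter
    rng = np.random.default_rng(seed)

    model, predict_fn = refit(np.asarray(X, float), y, n_components)
    original_r2 = r_squared(y, np.asarray(predict_fn(X)).ravel())
    original_q2 = cross_validate(X, y, n_components, scheme, refit=refit).q2

    r2_ys, q2_ys = [], []
    for _ in range(n_scrambles):
        perm = rng.permutation(len(y))
        while np.array_equal(perm, np.arange(len(y))):
            perm = rng.permutation(len(y))
        ys = y[perm]
        m, pf = refit(np.asarray(X, float), ys, n_components)
        r2_ys.append(r_squared(ys, np.asarray(pf(X)).ravel()))
        q2_ys.append(cross_validate(X, ys, n_components, scheme, refit=refit).q2)

    return ScramblingReport(
        n_scrambles=n_scrambles,
        seed=seed,
        r2_ys=r2_ys,
        q2_ys=q2_ys,
        original_r2=original_r2,
        original_q2=original_q2,
    )


def external_predict(
    model: PlsModel,
    test_ds: QsarDataset,
    grid: GridSpec,
    probe: Probe,
    cutoff: float,
    dielectric="distance_dependent",
) -> tuple[float, float, dict[str, float]]:
    """Predict an external test set on the training grid and settings.

    Fields are computed for the test molecules on the *model's* grid; the
    model's column provenance selects exactly the retained training
    columns.  Molecules with atoms outside the lattice box draw a warning
    (their fields are truncated at the box) but are still predicted.

    Returns ``(sdep_ext, r2_pred, predictions)``.
    """
    if not model.column_provenance:
        raise ValueError("model carries no column provenance")
    missing = [m.mol_id for m in test_ds.molecules
               if m.mol_id not in test_ds.activities]
    if missing:
        raise ValueError(f"test molecules lack activities: {missing}")

    outside = [
        m.mol_id for m in test_ds.molecules
        if not bool(np.all(grid.contains(m.coords_array())))
    ]
    if outside:
        warnings.warn(
            f"test molecule(s) extend outside the training lattice box "
            f"(fields truncated at the box): {outside}",
            stacklevel=2,
        )

    steric, ele = compute_mif(test_ds, grid, probe, cutoff, dielectric=dielectric)
    by_type = {"steric": steric.matrix, "electrostatic": ele.matrix}
    cols = [by_type[t][:, i] for t, i in model.column_provenance]
    X_test = np.stack(cols, axis=1)

    y_hat = predict(model, X_test)
    ids = test_ds.mol_ids
    y_obs = test_ds.p_values(ids)
    predictions = {i: float(v) for i, v in zip(ids, y_hat)}
    sdep_ext = sd_error(y_obs, y_hat, kind="SDEP")
    # r2_pred is undefined for a single test molecule or a constant response
    r2_pred = (
        r_squared(y_obs, y_hat)
        if len(y_obs) >= 2 and np.ptp(y_obs) > 0 else float("nan")
    )
    return sdep_ext, r2_pred, predictions
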