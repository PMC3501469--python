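"""Cormack-Jolly-Seber likelihood engine with a design-matrix model grammar.

Implements the open-population CJS likelihood for single-release encounter
histories on a logit link, with:

* a mini-grammar for survival/detection formulas, e.g.
  ``"phi ~ segment * SkokH + rd; p ~ segment + RM:line; fix p[JDF]=0.685"``;
* treatment-coded design matrices over grouping factors (segment,
  population, reartype, hatchery, SkokH, DuckH, year) and standardized
  covariates (rd, L, K);
* the ``RM:line`` term giving each river-mouth line its own detection
  probability at the first occasion while later lines share parameters;
* real-parameter fixing (the terminal-line detection probability is fixed
  by default configs because terminal survival and detection are otherwise
  confounded);
* quasi-Newton maximum likelihood, numerical-Hessian covariance, and
  delta-method real-scale estimates.

The likelihood factorizes each history into survival/detection terms up to
the last detection and the recursive never-seen-again tail
``chi_j = (1 - phi_j) + phi_j (1 - p_{j+1}) chi_{j+1}`` with ``chi_T = 1``.
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from . import defaults
from .io_model import (
    EncounterHistory,
    FishRecord,
    HATCHERY_OF,
    Population,
)

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FitResult",
    "parse_model",
    "build_design",
    "neg_loglik",
    "fit",
    "profile_confounding",
    "cell_estimates",
]

log = logging.getLogger(__name__)

_EPS = 1e-12
_PENALTY = 1e10

PHI_FACTORS = ("segment", "population", "reartype", "hatchery", "SkokH", "DuckH", "year")
P_FACTORS = ("segment", "year")
COVARIATE_ALIASES = {"rd": "rd", "L": "L", "length": "L", "K": "K", "k": "K"}


class ModelSpecError(ValueError):
    """Unknown term or malformed model string."""


@dataclass(frozen=True)
class ModelSpec:
    """Parsed phi/p formulas plus fixed real-parameter assignments.

    Terms are tuples of base names; ``("segment", "SkokH")`` is the
    segment-by-group interaction. ``fixed`` holds ``(param, selector,
    value)`` triples, e.g. ``("p", "JDF", 0.685)``.
    """

    phi_terms: tuple
    p_terms: tuple
    fixed: tuple = ()

    def __str__(self) -> str:
        def side(terms):
            return " + ".join(":".join(t) for t in terms) or "1"

        s = f"phi ~ {side(self.phi_terms)}; p ~ {side(self.p_terms)}"
        for param, sel, val in self.fixed:
            s += f"; fix {param}[{sel}]={val}"
        return s


def _expand_terms(rhs: str, special: Sequence[str] = ()) -> tuple:
    """Expand a formula right-hand side into term tuples.

    ``a * b`` becomes ``a + b + a:b``; ``a:b`` is a bare interaction.
    Special tokens (``RM:line``) pass through as single-name terms.
    """
    terms: list[tuple] = []
    rhs = rhs.strip()
    if rhs in ("", "1"):
        return ()
    for token in (t.strip() for t in rhs.split("+")):
        if not token:
            continue
        if token in special:
            _append_unique(terms, (token,))
        elif "*" in token:
            parts = [p.strip() for p in token.split("*")]
            for r in range(1, len(parts) + 1):
                for combo in itertools.combinations(parts, r):
                    _append_unique(terms, tuple(combo))
        elif ":" in token:
            _append_unique(terms, tuple(p.strip() for p in token.split(":")))
        else:
            _append_unique(terms, (token,))
    return tuple(terms)


def _append_unique(terms: list, term: tuple) -> None:
    if term not in terms:
        terms.append(term)


_FIX_RE = re.compile(r"fix\s+(phi|p)\s*\[\s*([^\]]+?)\s*\]\s*=\s*([-\d.eE]+)")


def parse_model(model_string: str) -> ModelSpec:
    """Parse ``"phi ~ ...; p ~ ...; fix p[JDF]=0.685"`` into a ModelSpec."""
    phi_terms = p_terms = None
    fixed = []
    for clause in (c.strip() for c in model_string.split(";")):
        if not clause:
            continue
        m = _FIX_RE.fullmatch(clause)
        if m:
            fixed.append((m.group(1), m.group(2), float(m.group(3))))
            continue
        if "~" not in clause:
            raise ModelSpecError(f"cannot parse clause {clause!r}")
        lhs, rhs = (s.strip() for s in clause.split("~", 1))
        if lhs in ("phi", "Phi"):
            phi_terms = _expand_terms(rhs)
        elif lhs == "p":
            p_terms = _expand_terms(rhs, special=("RM:line",))
        else:
            raise ModelSpecError(f"unknown parameter {lhs!r}")
    if phi_terms is None or p_terms is None:
        raise ModelSpecError("model string must define both phi and p")
    spec = ModelSpec(phi_terms, p_terms, tuple(fixed))
    _validate_terms(spec)
    return spec


def _validate_terms(spec: ModelSpec) -> None:
    for term in spec.phi_terms:
        for name in term:
            if name not in PHI_FACTORS and name not in COVARIATE_ALIASES:
                raise ModelSpecError(f"unknown phi term {name!r}")
    for term in spec.p_terms:
        if term == ("RM:line",):
            continue
        for name in term:
            if name not in P_FACTORS and name not in COVARIATE_ALIASES:
                raise ModelSpecError(f"unknown p term {name!r}")


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Per-cell design matrices for phi (fish x segment) and p (fish x
    occasion), with fixed-cell masks, column metadata, and the covariate
    standardization transforms."""

    X_phi: np.ndarray  # (n, T, k_phi)
    X_p: np.ndarray  # (n, T, k_p)
    phi_names: list
    p_names: list
    fixed_phi: np.ndarray  # (n, T) float, NaN where free
    fixed_p: np.ndarray  # (n, T) float, NaN where free
    covariate_cols: np.ndarray  # bool over k_phi + k_p
    transforms: dict
    phi_factors: pd.DataFrame  # per-fish factor values used by phi formula
    p_factors: pd.DataFrame
    segment_labels: list
    occasion_labels: list
    dropped: list = field(default_factory=list)

    @property
    def n_fish(self) -> int:
        return self.X_phi.shape[0]

    @property
    def T(self) -> int:
        return self.X_phi.shape[1]

    @property
    def k_total(self) -> int:
        return self.X_phi.shape[2] + self.X_p.shape[2]

    def active_columns(self) -> np.ndarray:
        """Columns with any leverage on a non-fixed cell.

        Columns supported only by fixed cells (e.g. the terminal-occasion
        dummy when terminal p is fixed) are structurally counted but pinned
        during optimization.
        """
        free_phi = np.isnan(self.fixed_phi)
        free_p = np.isnan(self.fixed_p)
        act_phi = (np.abs(self.X_phi[free_phi]) > 0).any(axis=0) if free_phi.any() \
            else np.zeros(self.X_phi.shape[2], bool)
        act_p = (np.abs(self.X_p[free_p]) > 0).any(axis=0) if free_p.any() \
            else np.zeros(self.X_p.shape[2], bool)
        return np.concatenate([act_phi, act_p])


def _factor_series(records, name, rm_line_of) -> tuple:
    """(values per fish, ordered levels) for a fish-level factor."""
    if name == "population":
        vals = [r.population.value for r in records]
        levels = [p.value for p in Population if p.value in set(vals)]
    elif name == "reartype":
        vals = [r.origin.value for r in records]
        levels = [l for l in ("wild", "hatchery") if l in set(vals)]
    elif name == "hatchery":
        vals = [HATCHERY_OF[r.population] for r in records]
        levels = [l for l in ("wild", "McKernan", "Lilliwaup") if l in set(vals)]
    elif name == "SkokH":
        vals = ["SkokH" if r.population is Population.SkokomishH else "other" for r in records]
        levels = [l for l in ("other", "SkokH") if l in set(vals)]
    elif name == "DuckH":
        vals = ["DuckH" if r.population is Population.DuckabushH else "other" for r in records]
        levels = [l for l in ("other", "DuckH") if l in set(vals)]
    elif name == "year":
        vals = [str(r.year) for r in records]
        levels = sorted(set(vals))
    else:
        raise ModelSpecError(f"unknown factor {name!r}")
    return np.asarray(vals, dtype=object), levels


def _covariate_values(records, name) -> np.ndarray:
    attr = {"rd": "release_date", "L": "fork_length_mm", "K": "condition_factor"}[name]
    return np.array([getattr(r, attr) for r in records], dtype=float)


def _block_columns(
    terms, records, T, cell_labels, rm_line_of, transforms, is_p
) -> tuple:
    """Build one block (phi or p) as a list of (name, (n, T) array,
    is_covariate) column triples, intercept first."""
    n = len(records)
    ones = np.ones((n, T))
    cols = [("(Intercept)", ones, False)]
    cell_dummies = {
        lab: np.tile((np.arange(T) == j).astype(float), (n, 1))
        for j, lab in enumerate(cell_labels)
    }
    for term in terms:
        if term == ("RM:line",):
            rm_lines = np.asarray([rm_line_of[r.population] for r in records], object)
            occ0 = cell_dummies[cell_labels[0]]
            for lvl in sorted(set(rm_lines)):
                ind = (rm_lines == lvl).astype(float)[:, None] * occ0
                cols.append((f"RM:line[{lvl}]", ind, False))
            continue
        parts = []  # list of lists of (suffix, (n, T) array, is_cov)
        for name in term:
            if name == "segment":
                parts.append(
                    [(f"segment[{lab}]", cell_dummies[lab], False) for lab in cell_labels[1:]]
                )
            elif name in COVARIATE_ALIASES:
                cname = COVARIATE_ALIASES[name]
                raw = _covariate_values(records, cname)
                if cname not in transforms:
                    mu, sd = float(raw.mean()), float(raw.std())
                    transforms[cname] = (mu, sd if sd > 0 else 1.0)
                mu, sd = transforms[cname]
                z = (raw - mu) / sd
                parts.append([(cname, np.tile(z[:, None], (1, T)), True)])
            else:
                vals, levels = _factor_series(records, name, rm_line_of)
                parts.append(
                    [
                        (f"{name}[{lvl}]", np.tile((vals == lvl).astype(float)[:, None], (1, T)), False)
                        for lvl in levels[1:]
                    ]
                )
        for combo in itertools.product(*parts):
            name = ":".join(c[0] for c in combo)
            arr = ones.copy()
            for _, a, _ in combo:
                arr = arr * a
            cols.append((name, arr, any(c[2] for c in combo)))
    return cols


def _greedy_rank_filter(matrix: np.ndarray, names, tol: float = 1e-8):
    """Keep a maximal left-to-right independent column subset (QR-style)."""
    keep, dropped = [], []
    basis = np.zeros((matrix.shape[0], 0))
    for j in range(matrix.shape[1]):
        v = matrix[:, j]
        resid = v - basis @ (basis.T @ v)
        norm = np.linalg.norm(resid)
        if norm > tol * max(1.0, np.linalg.norm(v)):
            keep.append(j)
            basis = np.concatenate([basis, (resid / norm)[:, None]], axis=1)
        else:
            dropped.append(names[j])
    return keep, dropped


def _resolve_fixed(spec, design_shape, segment_labels, occasion_labels):
    """Fixed-cell masks from (param, selector, value) triples. Selectors
    name a segment/occasion label or 1-based index."""
    n, T = design_shape
    fixed_phi = np.full((n, T), np.nan)
    fixed_p = np.full((n, T), np.nan)
    for param, sel, val in spec.fixed:
        labels = segment_labels if param == "phi" else occasion_labels
        if sel in labels:
            j = labels.index(sel)
        else:
            try:
                j = int(sel) - 1
            except ValueError as exc:
                raise ModelSpecError(f"unknown fixed selector {sel!r}") from exc
            if not 0 <= j < T:
                raise ModelSpecError(f"fixed selector {sel!r} out of range")
        (fixed_phi if param == "phi" else fixed_p)[:, j] = val
    return fixed_phi, fixed_p


def build_design(
    spec: ModelSpec,
    histories: Sequence[EncounterHistory],
    records: Sequence[FishRecord] | None = None,
    rm_line_of: Mapping | None = None,
) -> DesignMatrices:
    """Treatment-coded design matrices for a model spec.

    Aliased columns are dropped deterministically left-to-right (logged);
    the rank computation spans all cells including fixed ones, so the
    structural parameter count matches MARK-style reporting even when a
    column only touches fixed cells.
    """
    if records is None:
        records = [h.record for h in histories]
        if any(r is None for r in records):
            raise ValueError("histories must carry FishRecords or records must be given")
    rm_line_of = defaults.RM_LINE_OF if rm_line_of is None else rm_line_of
    T = len(histories[0].history) - 1
    seg_labels = list(defaults.SEGMENT_NAMES) if T == 4 else [f"s{j+1}" for j in range(T)]
    occ_labels = list(defaults.OCCASION_LINES) if T == 4 else [f"o{j+1}" for j in range(T)]

    transforms: dict = {}
    phi_cols = _block_columns(spec.phi_terms, records, T, seg_labels, rm_line_of, transforms, False)
    p_cols = _block_columns(spec.p_terms, records, T, occ_labels, rm_line_of, transforms, True)

    n = len(records)
    phi_long = np.stack([c[1] for c in phi_cols], axis=2).reshape(n * T, -1)
    p_long = np.stack([c[1] for c in p_cols], axis=2).reshape(n * T, -1)
    big = np.block(
        [
            [phi_long, np.zeros((n * T, p_long.shape[1]))],
            [np.zeros((n * T, phi_long.shape[1])), p_long],
        ]
    )
    names = [f"phi:{c[0]}" for c in phi_cols] + [f"p:{c[0]}" for c in p_cols]
    keep, dropped = _greedy_rank_filter(big, names)
    if dropped:
        log.warning("dropping aliased design column(s): %s", dropped)
    kphi = len(phi_cols)
    keep_phi = [j for j in keep if j < kphi]
    keep_p = [j - kphi for j in keep if j >= kphi]

    X_phi = np.stack([phi_cols[j][1] for j in keep_phi], axis=2)
    X_p = np.stack([p_cols[j][1] for j in keep_p], axis=2)
    covariate_cols = np.array(
        [phi_cols[j][2] for j in keep_phi] + [p_cols[j][2] for j in keep_p]
    )
    fixed_phi, fixed_p = _resolve_fixed(spec, (n, T), seg_labels, occ_labels)

    factor_names_phi = sorted(
        {nm for t in spec.phi_terms for nm in t if nm in PHI_FACTORS and nm != "segment"}
    )
    phi_factors = pd.DataFrame(
        {nm: _factor_series(records, nm, rm_line_of)[0] for nm in factor_names_phi},
        index=[r.fish_id for r in records],
    )
    p_special = any(t == ("RM:line",) for t in spec.p_terms)
    p_factors = pd.DataFrame(index=[r.fish_id for r in records])
    if p_special:
        p_factors["rm_line"] = [rm_line_of[r.population] for r in records]
    for nm in sorted({nm for t in spec.p_terms for nm in t if nm in P_FACTORS and nm != "segment"}):
        p_factors[nm] = _factor_series(records, nm, rm_line_of)[0]

    return DesignMatrices(
        X_phi=X_phi,
        X_p=X_p,
        phi_names=[phi_cols[j][0] for j in keep_phi],
        p_names=[p_cols[j][0] for j in keep_p],
        fixed_phi=fixed_phi,
        fixed_p=fixed_p,
        covariate_cols=covariate_cols,
        transforms=transforms,
        phi_factors=phi_factors,
        p_factors=p_factors,
        segment_labels=seg_labels,
        occasion_labels=occ_labels,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _history_matrix(histories) -> np.ndarray:
    if isinstance(histories, np.ndarray):
        return np.asarray(histories, dtype=int)
    return np.stack([h.history for h in histories]).astype(int)


def cjs_loglik_real(
    phi: np.ndarray, p: np.ndarray, hist: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """CJS log-likelihood from real-scale per-cell parameter arrays.

    ``phi`` and ``p`` are (n, T); ``hist`` is (n, T+1) with column 0 the
    release occasion.
    """
    phi = np.clip(np.asarray(phi, float), _EPS, 1 - _EPS)
    p = np.clip(np.asarray(p, float), _EPS, 1 - _EPS)
    hist = _history_matrix(hist)
    n, T = phi.shape
    obs = hist[:, 1:]
    last = (hist * np.arange(T + 1)).max(axis=1)

    chi = np.ones((n, T + 1))
    for j in range(T - 1, -1, -1):
        chi[:, j] = (1 - phi[:, j]) + phi[:, j] * (1 - p[:, j]) * chi[:, j + 1]

    contrib = np.log(phi) + np.where(obs == 1, np.log(p), np.log1p(-p))
    mask = np.arange(1, T + 1)[None, :] <= last[:, None]
    ll = (contrib * mask).sum(axis=1) + np.log(chi[np.arange(n), last])
    if weights is None:
        return float(ll.sum())
    return float(ll @ weights)


def _real_params(beta: np.ndarray, design: DesignMatrices):
    kphi = design.X_phi.shape[2]
    eta_phi = design.X_phi @ beta[:kphi]
    eta_p = design.X_p @ beta[kphi:]
    phi = expit(eta_phi)
    p = expit(eta_p)
    fmask = ~np.isnan(design.fixed_phi)
    phi = np.where(fmask, design.fixed_phi, phi)
    pmask = ~np.isnan(design.fixed_p)
    p = np.where(pmask, design.fixed_p, p)
    return phi, p


def neg_loglik(
    beta: np.ndarray,
    design: DesignMatrices,
    histories,
    weights: np.ndarray | None = None,
) -> float:
    """Negative CJS log-likelihood at coefficient vector ``beta``
    (phi block then p block). Non-finite ``beta`` returns a large penalty
    instead of raising."""
    beta = np.asarray(beta, float)
    if not np.all(np.isfinite(beta)):
        return _PENALTY
    phi, p = _real_params(beta, design)
    return -cjs_loglik_real(phi, p, histories, weights)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted CJS model: coefficients, covariance, real-scale estimates."""

    spec: ModelSpec
    beta: np.ndarray
    vcov: np.ndarray  # over all columns; NaN rows/cols for pinned params
    loglik: float
    n_params: int  # structural K used by QAICc (excludes fixed reals)
    converged: bool
    real_phi: np.ndarray  # (n, T)
    real_p: np.ndarray
    se_phi: np.ndarray
    se_p: np.ndarray
    design: DesignMatrices
    n_fish: int
    message: str = ""

    def to_json(self) -> str:
        payload = {
            "model": str(self.spec),
            "beta": dict(
                zip(
                    [f"phi:{n}" for n in self.design.phi_names]
                    + [f"p:{n}" for n in self.design.p_names],
                    np.round(self.beta, 6).tolist(),
                )
            ),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "n_fish": self.n_fish,
        }
        return json.dumps(payload, indent=2)


def _collapse(design: DesignMatrices, hist: np.ndarray):
    """Collapse fish with identical (history, design rows, fixed cells) to
    weighted unique rows; a large speedup for factor-only models."""
    n = hist.shape[0]
    flat = np.concatenate(
        [
            hist.reshape(n, -1).astype(float),
            design.X_phi.reshape(n, -1),
            design.X_p.reshape(n, -1),
            np.nan_to_num(design.fixed_phi, nan=-1.0),
            np.nan_to_num(design.fixed_p, nan=-1.0),
        ],
        axis=1,
    )
    _, idx, counts = np.unique(flat, axis=0, return_index=True, return_counts=True)
    sub = DesignMatrices(
        X_phi=design.X_phi[idx],
        X_p=design.X_p[idx],
        phi_names=design.phi_names,
        p_names=design.p_names,
        fixed_phi=design.fixed_phi[idx],
        fixed_p=design.fixed_p[idx],
        covariate_cols=design.covariate_cols,
        transforms=design.transforms,
        phi_factors=design.phi_factors.iloc[idx] if len(design.phi_factors) == n else design.phi_factors,
        p_factors=design.p_factors.iloc[idx] if len(design.p_factors) == n else design.p_factors,
        segment_labels=design.segment_labels,
        occasion_labels=design.occasion_labels,
    )
    return sub, hist[idx], counts.astype(float)


def _numerical_hessian(fun, x, step: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * step**2)
    return H


def fit(
    spec: ModelSpec | str,
    histories: Sequence[EncounterHistory],
    records: Sequence[FishRecord] | None = None,
    rm_line_of: Mapping | None = None,
    c_hat: float = 1.0,
    max_restarts: int = 3,
) -> FitResult:
    """Maximum-likelihood fit of a CJS model spec.

    Starts from ``beta = 0`` (real scale 0.5), restarting from jittered
    points on non-convergence. The covariance matrix is the inverse
    numerical Hessian at the optimum; real-scale SEs use the delta method
    and are inflated by ``sqrt(c_hat)`` when ``c_hat > 1``. Non-convergence
    and singular Hessians are flagged on the result, never raised.
    """
    if isinstance(spec, str):
        spec = parse_model(spec)
    design = build_design(spec, histories, records, rm_line_of)
    hist = _history_matrix(histories)
    if hist[:, 1:].sum() == 0:
        raise ValueError("no detections beyond release; CJS parameters inestimable")
    sub, uhist, weights = _collapse(design, hist)

    active = design.active_columns()
    k_total = design.k_total
    n_active = int(active.sum())

    def objective(x_active: np.ndarray) -> float:
        beta = np.zeros(k_total)
        beta[active] = x_active
        return neg_loglik(beta, sub, uhist, weights)

    rng = np.random.default_rng(0)
    best = None
    x0 = np.zeros(n_active)
    message = ""
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(objective, x0, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-6})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        # BFGS often reports precision loss at a perfectly good optimum;
        # accept any stationary point rather than burning restarts
        if res.success or np.linalg.norm(res.jac) < 1e-3:
            break
        x0 = rng.normal(0.0, 0.5, size=n_active)
        message = f"restarted {attempt + 1}x"
    converged = bool(best.success) or np.linalg.norm(best.jac) < 1e-3

    beta = np.zeros(k_total)
    beta[active] = best.x
    loglik = -float(best.fun)

    vcov = np.full((k_total, k_total), np.nan)
    try:
        H = _numerical_hessian(objective, best.x)
        vcov_active = np.linalg.inv(H)
        if np.any(np.diag(vcov_active) < 0):
            raise np.linalg.LinAlgError("negative variance")
        ix = np.ix_(active, active)
        vcov[ix] = vcov_active
    except np.linalg.LinAlgError as exc:
        message = (message + f"; singular Hessian: {exc}").strip("; ")
        log.warning("vcov unavailable: %s", exc)

    phi, p = _real_params(beta, design)
    kphi = design.X_phi.shape[2]
    hessian_ok = not np.isnan(vcov[np.ix_(active, active)]).any() if n_active else True
    if hessian_ok:
        se_phi = _delta_se(design.X_phi, vcov[:kphi, :kphi], phi)
        se_p = _delta_se(design.X_p, vcov[kphi:, kphi:], p)
    else:
        se_phi = np.full_like(phi, np.nan)
        se_p = np.full_like(p, np.nan)
    se_phi[~np.isnan(design.fixed_phi)] = 0.0
    se_p[~np.isnan(design.fixed_p)] = 0.0
    if c_hat > 1:
        se_phi = se_phi * np.sqrt(c_hat)
        se_p = se_p * np.sqrt(c_hat)

    return FitResult(
        spec=spec,
        beta=beta,
        vcov=vcov,
        loglik=loglik,
        n_params=k_total,
        converged=converged,
        real_phi=phi,
        real_p=p,
        se_phi=se_phi,
        se_p=se_p,
        design=design,
        n_fish=len(hist),
        message=message,
    )


def _delta_se(X: np.ndarray, vcov_block: np.ndarray, real: np.ndarray) -> np.ndarray:
    """Delta-method SE for inverse-logit(X beta), NaN-safe for pinned
    coefficients (treated as zero-variance)."""
    V = np.nan_to_num(vcov_block, nan=0.0)
    var_eta = np.einsum("ntk,kl,ntl->nt", X, V, X)
    var_eta = np.clip(var_eta, 0.0, None)
    return real * (1 - real) * np.sqrt(var_eta)


def cell_estimates(result: FitResult, kind: str = "phi", zero_covariates: bool = True) -> pd.DataFrame:
    """Unique real-scale cell estimates, grouped by segment/occasion and
    the formula's grouping-factor values.

    With ``zero_covariates`` (default) individual covariates are evaluated
    at their standardized mean (0), giving one typical estimate per cell.
    """
    design = result.design
    kphi = design.X_phi.shape[2]
    if kind == "phi":
        X, labels = design.X_phi, design.segment_labels
        beta, V = result.beta[:kphi], result.vcov[:kphi, :kphi]
        factors, fixed = design.phi_factors, design.fixed_phi
        cov_cols = design.covariate_cols[:kphi]
    else:
        X, labels = design.X_p, design.occasion_labels
        beta, V = result.beta[kphi:], result.vcov[kphi:, kphi:]
        factors, fixed = design.p_factors, design.fixed_p
        cov_cols = design.covariate_cols[kphi:]
    X = X.copy()
    if zero_covariates:
        X[:, :, cov_cols] = 0.0
    eta = X @ beta
    real = expit(eta)
    fmask = ~np.isnan(fixed)
    real = np.where(fmask, fixed, real)
    se = _delta_se(X, V, real)
    se[fmask] = 0.0

    n, T = real.shape
    frame = factors.reset_index(drop=True)
    rows = []
    for j in range(T):
        df = frame.copy()
        df["cell"] = labels[j]
        df["estimate"] = real[:, j]
        df["se"] = se[:, j]
        df["fixed"] = fmask[:, j]
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    group_cols = ["cell"] + [c for c in factors.columns]
    out = (
        out.groupby(group_cols, sort=False, dropna=False)
        .agg(estimate=("estimate", "mean"), se=("se", "mean"), fixed=("fixed", "any"))
        .reset_index()
    )
    order = {lab: i for i, lab in enumerate(labels)}
    return out.sort_values("cell", key=lambda s: s.map(order), kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# terminal-occasion confounding
# ---------------------------------------------------------------------------

def profile_confounding(
    result: FitResult,
    histories=None,
    n_grid: int = 25,
    tol: float = 1e-6,
) -> dict:
    """Check identifiability of the terminal survival/detection pair.

    Without a fixed terminal p, only the product ``phi_T * p_T`` is
    identifiable: sliding along the compensating ridge (product held at
    its fitted value) leaves the likelihood flat within ``tol``. Fixing
    the terminal p removes the ridge.
    """
    design = result.design
    hist = _history_matrix(histories) if histories is not None else None
    if hist is None:
        raise ValueError("histories are required to evaluate the ridge")
    terminal_fixed = bool((~np.isnan(design.fixed_p[:, -1])).all())
    phi0, p0 = result.real_phi.copy(), result.real_p.copy()
    base = cjs_loglik_real(phi0, p0, hist)
    product = float(np.mean(phi0[:, -1] * p0[:, -1]))

    if terminal_fixed:
        # vary terminal phi alone; likelihood must move
        deltas = []
        for f in np.linspace(0.7, 1.3, 7):
            phi = phi0.copy()
            phi[:, -1] = np.clip(phi0[:, -1] * f, 1e-6, 1 - 1e-6)
            deltas.append(abs(cjs_loglik_real(phi, p0, hist) - base))
        return {
            "terminal_p_fixed": True,
            "ridge_flat": False,
            "identifiable": True,
            "loglik_variation": float(max(deltas)),
            "product": product,
        }

    # slide along the ridge: phi_T *= f, p_T /= f keeps every fish's
    # terminal product (and hence the likelihood) unchanged iff confounded
    f_lo = float(np.max(p0[:, -1])) + 1e-9
    f_hi = 1.0 / (float(np.max(phi0[:, -1])) + 1e-9)
    variations = []
    for f in np.linspace(max(f_lo, 0.05), max(f_hi, f_lo + 1e-6), n_grid):
        phi = phi0.copy()
        p = p0.copy()
        phi[:, -1] = np.clip(phi0[:, -1] * f, _EPS, 1 - _EPS)
        p[:, -1] = np.clip(p0[:, -1] / f, _EPS, 1 - _EPS)
        variations.append(abs(cjs_loglik_real(phi, p, hist) - base))
    variation = float(max(variations)) if variations else np.inf
    return {
        "terminal_p_fixed": False,
        "ridge_flat": variation < tol,
        "identifiable": False,
        "loglik_variation": variation,
        "product": product,
    }
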