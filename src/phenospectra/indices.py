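"""Spectral indices: catalog, expression evaluation, and data-driven discovery.

An index is an expression tree over band references.  A band reference is
either a single wavelength (nearest grid band is used) or an [lo, hi] range
(unweighted mean reflectance over the member bands).  Two discovery methods
are implemented:

* :func:`exhaustive_pair_search` scores every simple ratio rho_i/rho_j and
  normalized difference (rho_i - rho_j)/(rho_i + rho_j) against a trait and
  returns the best-correlated form.
* :func:`greedy_index_builder` starts from the single best-correlated band and
  greedily composes it with further bands through the binary operations
  {+, -, x, /} until the correlation stabilizes or four distinct wavelengths
  are in use.

Both can rank candidates by ordinary Pearson correlation or by repeated-
measures correlation (the common within-subject correlation, appropriate when
the same plants are measured repeatedly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BandRef",
    "Expr",
    "Band",
    "Const",
    "BinOp",
    "IndexDefinition",
    "SearchResult",
    "band_value",
    "compute_index",
    "index_catalog",
    "rmcorr",
    "exhaustive_pair_search",
    "greedy_index_builder",
    "SEARCH_RANGE_NM",
]

#: wavelength window used by both discovery methods; bands outside this window
#: sit at the noisy sensor edges and are never searched
SEARCH_RANGE_NM = (480.0, 2470.0)


# --------------------------------------------------------------------------
# Expression trees
# --------------------------------------------------------------------------

class Expr:
    """Base class for index expression nodes."""

    def evaluate(self, wavelengths: np.ndarray, spectrum: np.ndarray) -> float:
        raise NotImplementedError

    def bands(self) -> list:
        """All band references appearing in the expression."""
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    def __add__(self, other):
        return BinOp("+", self, _as_expr(other))

    def __sub__(self, other):
        return BinOp("-", self, _as_expr(other))

    def __mul__(self, other):
        return BinOp("*", self, _as_expr(other))

    def __truediv__(self, other):
        return BinOp("/", self, _as_expr(other))

    def __rmul__(self, other):
        return BinOp("*", _as_expr(other), self)

    def __rsub__(self, other):
        return BinOp("-", _as_expr(other), self)


def _as_expr(x) -> "Expr":
    if isinstance(x, Expr):
        return x
    return Const(float(x))


@dataclass(frozen=True)
class Band(Expr):
    """Band reference: a single centre wavelength or an inclusive nm range."""

    lo: float
    hi: float | None = None

    def evaluate(self, wavelengths, spectrum):
        return band_value(wavelengths, spectrum, self)

    def bands(self):
        return [self]

    def to_dict(self):
        if self.hi is None:
            return {"band": self.lo}
        return {"band": [self.lo, self.hi]}

    def __repr__(self):
        if self.hi is None:
            return f"rho({self.lo:g})"
        return f"rho({self.lo:g}-{self.hi:g})"


@dataclass(frozen=True)
class Const(Expr):
    value: float

    def evaluate(self, wavelengths, spectrum):
        return self.value

    def bands(self):
        return []

    def to_dict(self):
        return {"const": self.value}

    def __repr__(self):
        return f"{self.value:g}"


@dataclass(frozen=True)
class BinOp(Expr):
    op: str
    left: Expr
    right: Expr

    def evaluate(self, wavelengths, spectrum):
        a = self.left.evaluate(wavelengths, spectrum)
        b = self.right.evaluate(wavelengths, spectrum)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        if self.op == "/":
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.divide(a, b)
            return np.where(b == 0, np.nan, out) if np.ndim(out) else (
                np.nan if b == 0 else out
            )
        raise ValueError(f"unknown operator {self.op!r}")

    def bands(self):
        return self.left.bands() + self.right.bands()

    def to_dict(self):
        return {"op": self.op, "left": self.left.to_dict(),
                "right": self.right.to_dict()}

    def __repr__(self):
        return f"({self.left!r} {self.op} {self.right!r})"


def expr_from_dict(d: dict) -> Expr:
    if "const" in d:
        return Const(d["const"])
    if "band" in d:
        b = d["band"]
        if isinstance(b, (list, tuple)):
            return Band(float(b[0]), float(b[1]))
        return Band(float(b))
    return BinOp(d["op"], expr_from_dict(d["left"]), expr_from_dict(d["right"]))


@dataclass
class IndexDefinition:
    """Named spectral index: an expression tree plus provenance."""

    name: str
    expression: Expr
    origin: str = "published"  # or "novel"

    def bands(self) -> list[Band]:
        return self.expression.bands()

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "origin": self.origin,
             "expression": self.expression.to_dict()}
        )

    @classmethod
    def from_json(cls, s: str) -> "IndexDefinition":
        d = json.loads(s)
        return cls(d["name"], expr_from_dict(d["expression"]), d["origin"])


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def band_value(wavelengths: np.ndarray, spectrum: np.ndarray, ref: Band):
    """Reflectance for a band reference on a wavelength grid.

    Singleton references use the nearest grid band; a request farther than half
    the local band spacing outside the grid is an error.  Range references
    average all bands with lo <= w <= hi (error if the range is empty).
    ``spectrum`` may be 1-D (bands,) or 2-D (observations, bands).
    """
    w = np.asarray(wavelengths, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    if ref.hi is None:
        half_step = 0.5 * float(np.median(np.diff(w))) if w.size > 1 else 0.0
        if ref.lo < w[0] - half_step or ref.lo > w[-1] + half_step:
            raise ValueError(
                f"band {ref.lo} nm outside grid {w[0]:.0f}-{w[-1]:.0f} nm"
            )
        return spectrum[..., int(np.argmin(np.abs(w - ref.lo)))]
    members = (w >= ref.lo) & (w <= ref.hi)
    if not members.any():
        raise ValueError(f"no grid bands inside range {ref.lo}-{ref.hi} nm")
    return spectrum[..., members].mean(axis=-1)


def compute_index(wavelengths: np.ndarray, spectrum: np.ndarray,
                  definition: IndexDefinition | Expr):
    """Evaluate an index on a spectrum (or a stack of spectra).

    Division by zero yields NaN rather than raising.
    """
    expr = definition.expression if isinstance(definition, IndexDefinition) else definition
    return expr.evaluate(np.asarray(wavelengths, float), np.asarray(spectrum, float))


# --------------------------------------------------------------------------
# Catalog (10 published + 10 novel definitions)
# --------------------------------------------------------------------------

def _b(nm):
    return Band(float(nm))


def _r(lo, hi):
    return Band(float(lo), float(hi))


def index_catalog() -> list[IndexDefinition]:
    """The evaluated index set: 10 published and 10 novel definitions.

    Wavelength placements follow the catalog's printed positions, which were
    chosen as the nearest available sensor bands (e.g. MCARI's rho_700 sits at
    699 nm, CRI1's rho_510 at 511 nm).
    """
    p = [
        IndexDefinition(
            "MCARI",
            ((_b(699) - _b(670)) - Const(0.2) * (_b(699) - _b(551)))
            * (_b(699) / _b(670)),
        ),
        IndexDefinition("CRI1", Const(1.0) / _b(511) - Const(1.0) / _b(551)),
        IndexDefinition("RGRI", _r(600, 700) / _r(500, 600)),
        IndexDefinition(
            "NDVI", (_r(800, 900) - _r(600, 700)) / (_r(800, 900) + _r(600, 700))
        ),
        IndexDefinition("MSI", _r(1550, 1650) / _r(760, 900)),
        IndexDefinition("WBI", _b(969) / _b(901)),
        IndexDefinition("PRI", (_b(532) - _b(570)) / (_b(532) + _b(570))),
        IndexDefinition("RVI_870/610", _r(865, 875) / _r(605, 615)),
        IndexDefinition("R_775/510", _r(750, 800) / _b(511)),
        IndexDefinition("RWC", _b(1432) / _b(1850)),
    ]
    n = [
        IndexDefinition("WCI", (_b(686) - _b(955)) / (_b(955) - _b(548)), "novel"),
        IndexDefinition("WPI1", (_r(660, 670) - _r(710, 720)) / _r(710, 720), "novel"),
        IndexDefinition(
            "WPI2",
            (_r(660, 670) + _b(1457)) / (_r(710, 720) + _b(1457)),
            "novel",
        ),
        IndexDefinition(
            "ARGI", (Const(2.0) * _r(600, 700)) / (_b(551) - _b(639)), "novel"
        ),
        IndexDefinition(
            "IND_715/655",
            (_r(710, 720) + _r(640, 670)) / (_r(710, 720) - _r(640, 670)),
            "novel",
        ),
        IndexDefinition("R_953/520", _b(953) / _b(520), "novel"),
        IndexDefinition("R_960/699", _b(960) / _b(699), "novel"),
        IndexDefinition("R_953/492", _b(953) / _b(492), "novel"),
        IndexDefinition(
            "NDI_1407/1862", (_b(1407) - _b(1862)) / (_b(1407) + _b(1862)), "novel"
        ),
        IndexDefinition("R_1451/1263", _b(1451) / _b(1263), "novel"),
    ]
    return p + n


def get_index(name: str) -> IndexDefinition:
    for d in index_catalog():
        if d.name == name:
            return d
    raise KeyError(f"no catalog index named {name!r}")


# --------------------------------------------------------------------------
# Correlation machinery
# --------------------------------------------------------------------------

def rmcorr(subject_ids: Sequence, x: np.ndarray, y: np.ndarray) -> float:
    """Repeated-measures correlation: common within-subject correlation.

    Each subject's observations are centered on that subject's means, removing
    between-subject variation; the Pearson correlation of the centered series
    is the shared within-subject correlation, with the sign of the common
    within-subject slope.  Subjects with a single observation contribute
    nothing and are dropped.
    """
    ids = np.asarray(subject_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = _center_within(ids, x, y)
    if xc.size < 2:
        raise ValueError("rmcorr needs at least one subject with >= 2 observations")
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0 or sy == 0:
        raise ValueError("zero within-subject variance")
    return float(np.sum(xc * yc) / (sx * sy))


def _center_within(ids: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Subject-mean-center x and y, keeping subjects with >= 2 observations."""
    xc = np.empty(0)
    yc = np.empty(0)
    parts_x, parts_y = [], []
    for uid in np.unique(ids):
        sel = ids == uid
        if np.count_nonzero(sel) < 2:
            continue
        parts_x.append(x[sel] - x[sel].mean())
        parts_y.append(y[sel] - y[sel].mean())
    if parts_x:
        xc = np.concatenate(parts_x)
        yc = np.concatenate(parts_y)
    return xc, yc


def _corr_columns(features: np.ndarray, y: np.ndarray,
                  subject_ids: np.ndarray | None) -> np.ndarray:
    """Pearson (or, with subject ids, repeated-measures) correlation of each
    feature column with y.  NaN feature entries disable a column (corr NaN).
    """
    feats = np.asarray(features, dtype=float)
    yv = np.asarray(y, dtype=float)
    if subject_ids is not None:
        ids = np.asarray(subject_ids)
        parts_f, parts_y = [], []
        for uid in np.unique(ids):
            sel = ids == uid
            if np.count_nonzero(sel) < 2:
                continue
            block = feats[sel]
            col_ok = ~np.isnan(block).all(axis=0)
            means = np.zeros(block.shape[1])
            means[col_ok] = np.nanmean(block[:, col_ok], axis=0)
            parts_f.append(block - means)
            parts_y.append(yv[sel] - yv[sel].mean())
        feats = np.concatenate(parts_f)
        yv = np.concatenate(parts_y)
    else:
        col_ok = ~np.isnan(feats).all(axis=0)
        means = np.zeros(feats.shape[1])
        means[col_ok] = np.nanmean(feats[:, col_ok], axis=0)
        feats = feats - means
        yv = yv - yv.mean()
    bad = np.isnan(feats).any(axis=0)
    feats = np.where(np.isnan(feats), 0.0, feats)
    num = feats.T @ yv
    den = np.sqrt(np.sum(feats**2, axis=0)) * np.sqrt(np.sum(yv**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(num / den, -1.0, 1.0)
    r[bad | (den == 0)] = np.nan
    return r


@dataclass
class SearchResult:
    """Outcome of a discovery run."""

    definition: IndexDefinition
    correlation: float
    correlation_kind: str
    trait_name: str
    search_trace: list[float] = field(default_factory=list)


def _restrict(wavelengths: np.ndarray, spectra: np.ndarray):
    w = np.asarray(wavelengths, dtype=float)
    keep = (w >= SEARCH_RANGE_NM[0]) & (w <= SEARCH_RANGE_NM[1])
    return w[keep], np.asarray(spectra, dtype=float)[:, keep]


def _check_trait(y: np.ndarray):
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")
    return y


def exhaustive_pair_search(
    wavelengths: np.ndarray,
    spectra: np.ndarray,
    trait: np.ndarray,
    correlation_kind: str = "pearson",
    subject_ids: Sequence | None = None,
    trait_name: str = "trait",
) -> SearchResult:
    """Method 1: score every two-band ratio and normalized difference.

    Ratios use ordered pairs (rho_i/rho_j differs from rho_j/rho_i); normalized
    differences use unordered pairs (the swap only flips the sign).  The form
    with the largest |correlation| wins; exact ties resolve to the earliest
    candidate in (i, j)-lexicographic order, ratios enumerated before
    normalized differences.
    """
    y = _check_trait(trait)
    if correlation_kind == "rmcorr":
        if subject_ids is None:
            raise ValueError("rmcorr requires subject_ids")
        ids = np.asarray(subject_ids)
    elif correlation_kind == "pearson":
        ids = None
    else:
        raise ValueError(f"unknown correlation kind {correlation_kind!r}")
    w, s = _restrict(wavelengths, spectra)
    n_bands = w.size
    best_r = 0.0
    best: tuple | None = None
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n_bands):
            col = s[:, [i]]
            ratios = np.where(s != 0, col / s, np.nan)
            ratios[:, i] = np.nan  # rho_i / rho_i is constant
            r = _corr_columns(ratios, y, ids)
            j = _first_argmax_abs(r)
            if j is not None and abs(r[j]) > abs(best_r) + 1e-15:
                best_r = float(r[j])
                best = ("ratio", i, j)
        for i in range(n_bands - 1):
            col = s[:, [i]]
            rest = s[:, i + 1:]
            denom = col + rest
            nd = np.where(denom != 0, (col - rest) / denom, np.nan)
            r = _corr_columns(nd, y, ids)
            j = _first_argmax_abs(r)
            if j is not None and abs(r[j]) > abs(best_r) + 1e-15:
                best_r = float(r[j])
                best = ("nd", i, i + 1 + j)
    if best is None:
        raise ValueError("no valid candidate pair (all correlations undefined)")
    kind, i, j = best
    bi, bj = Band(float(w[i])), Band(float(w[j]))
    if kind == "ratio":
        expr = bi / bj
        name = f"R_{w[i]:g}/{w[j]:g}"
    else:
        expr = (bi - bj) / (bi + bj)
        name = f"NDI_{w[i]:g}/{w[j]:g}"
    return SearchResult(
        IndexDefinition(name, expr, "novel"),
        best_r,
        correlation_kind,
        trait_name,
        [abs(best_r)],
    )


def _first_argmax_abs(r: np.ndarray):
    a = np.abs(r)
    if np.all(np.isnan(a)):
        return None
    return int(np.nanargmax(a))


def greedy_index_builder(
    wavelengths: np.ndarray,
    spectra: np.ndarray,
    trait: np.ndarray,
    correlation_kind: str = "pearson",
    subject_ids: Sequence | None = None,
    max_bands: int = 4,
    tol: float = 0.01,
    trait_name: str = "trait",
) -> SearchResult:
    """Method 2: grow an index greedily from the best single band.

    Step 1 picks the band whose reflectance correlates most strongly with the
    trait.  Each later step tries combining the current expression E with every
    unused band w through {E+w, E-w, w-E, E*w, E/w, w/E} and keeps the best
    combination, stopping once the |correlation| gain falls below ``tol`` or
    the index holds ``max_bands`` distinct wavelengths.
    """
    y = _check_trait(trait)
    if correlation_kind == "rmcorr":
        if subject_ids is None:
            raise ValueError("rmcorr requires subject_ids")
        ids = np.asarray(subject_ids)
    elif correlation_kind == "pearson":
        ids = None
    else:
        raise ValueError(f"unknown correlation kind {correlation_kind!r}")
    w, s = _restrict(wavelengths, spectra)

    r0 = _corr_columns(s, y, ids)
    i0 = _first_argmax_abs(r0)
    if i0 is None:
        raise ValueError("no band has a defined correlation with the trait")
    expr: Expr = Band(float(w[i0]))
    cur_vals = s[:, i0].copy()
    cur_r = float(r0[i0])
    used = {i0}
    trace = [abs(cur_r)]

    while len(used) < max_bands:
        candidates = [k for k in range(w.size) if k not in used]
        if not candidates:
            break
        cols = s[:, candidates]
        cv = cur_vals[:, np.newaxis]
        with np.errstate(divide="ignore", invalid="ignore"):
            forms = {
                "E+w": cv + cols,
                "E-w": cv - cols,
                "w-E": cols - cv,
                "E*w": cv * cols,
                "E/w": np.where(cols != 0, cv / cols, np.nan),
                "w/E": np.where(cv != 0, cols / cv, np.nan),
            }
        best_gain = -np.inf
        best_step = None
        for form, vals in forms.items():
            r = _corr_columns(vals, y, ids)
            j = _first_argmax_abs(r)
            if j is None:
                continue
            gain = abs(r[j]) - abs(cur_r)
            if gain > best_gain + 1e-15:
                best_gain = gain
                best_step = (form, candidates[j], float(r[j]), vals[:, j].copy())
        if best_step is None or best_gain < tol:
            break
        form, k, r_new, new_vals = best_step
        band = Band(float(w[k]))
        expr = {
            "E+w": lambda: expr + band,
            "E-w": lambda: expr - band,
            "w-E": lambda: band - expr,
            "E*w": lambda: expr * band,
            "E/w": lambda: expr / band,
            "w/E": lambda: band / expr,
        }[form]()
        cur_vals = new_vals
        cur_r = r_new
        used.add(k)
        trace.append(abs(cur_r))

    name = "GREEDY_" + "_".join(f"{w[k]:g}" for k in sorted(used))
    return SearchResult(
        IndexDefinition(name, expr, "novel"),
        cur_r,
        correlation_kind,
        trait_name,
        trace,
    )
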