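"""Likelihood-ratio tests and selective-pressure classification.

Fitted codon models (site, branch, branch-site and clade families) arrive as
:class:`ModelFit` records — identifier, log-likelihood, parameter count,
per-branch dN/dS (ω) estimates and per-site records — read from a neutral
TSV interchange format. Nested model pairs are compared with a likelihood
ratio test, D = 2(lnL_alt − lnL_null) against a χ² distribution with
df = Δ(free parameters); a conservative plain χ² is the default, with an
optional 50:50 point-mass/χ² boundary mixture for tests whose null pins a
parameter at a boundary (e.g. the branch-site null).

The classification scheme maps estimates to the display classes used when
painting results onto a tree:

* branch ω: < 0.2 purifying, 0.2–1 (inclusive) relaxed, > 1 positive,
  infinite saturated;
* site positive-selection p-values: < 0.01 strong, < 0.05 moderate, else ns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy.stats import chi2

from .errors import LRTError, ModelTSVError, TreekitError

_TSV_MAGIC = "#treekit-model-fit"
_TSV_VERSION = "1"

#: canonical nested (null, alternative) pairs per model family
NESTED_PAIRS: tuple[tuple[str, str], ...] = (
    ("M0", "M3"),          # site: one ratio vs discrete
    ("M1", "M2"),          # site: nearly-neutral vs positive selection
    ("M7", "M8"),          # site: beta vs beta + positive class
    ("M0", "free-ratio"),  # branch: one ratio vs one per branch
    ("M0", "b_free"),      # branch: marked-branch ratio free
    ("b_neut", "b_free"),  # branch: marked ratio =1 vs free
    ("bsA1", "bsA"),       # branch-site: null vs alternative
    ("M1", "bsC"),         # clade model C vs nearly-neutral
)


@dataclass(frozen=True)
class SiteRecord:
    """Per-alignment-column estimate from a site-wise model."""

    site_index: int
    omega: float
    p_value: float | None = None
    class_probabilities: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.site_index < 1:
            raise TreekitError("site_index is 1-based and must be >= 1")
        if self.omega < 0:
            raise TreekitError(f"site omega must be >= 0, got {self.omega}")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise TreekitError(f"p_value outside [0, 1]: {self.p_value}")
        if self.class_probabilities is not None:
            total = sum(self.class_probabilities)
            if abs(total - 1.0) > 1e-6:
                raise TreekitError(
                    f"class probabilities sum to {total}, expected 1")


@dataclass
class ModelFit:
    """One fitted evolutionary model."""

    model_id: str
    lnL: float
    n_params: int
    branch_omegas: dict[str, float] = field(default_factory=dict)
    sites: list[SiteRecord] = field(default_factory=list)

    def __post_init__(self):
        if not math.isfinite(self.lnL):
            raise TreekitError(f"lnL must be finite, got {self.lnL}")
        if self.n_params < 1:
            raise TreekitError(f"n_params must be >= 1, got {self.n_params}")
        for bid, w in self.branch_omegas.items():
            if w < 0 or math.isnan(w):
                raise TreekitError(f"omega for branch {bid!r} must be >= 0")


@dataclass(frozen=True)
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float


def lrt(null: ModelFit, alt: ModelFit, df: int | None = None,
        boundary_mixture: bool = False) -> LRTResult:
    """Likelihood ratio test of a nested model pair.

    ``df`` defaults to the parameter-count difference, but only for pairs in
    the registered nesting table (:data:`NESTED_PAIRS`); an unknown pair
    requires an explicit ``df`` so accidental non-nested comparisons fail
    loudly. D is clamped at zero (optimizer noise routinely makes the richer
    model land a hair below the null); a clamp triggers a warning, not an
    error. ``boundary_mixture=True`` halves the χ² tail probability, the
    50:50 mixture appropriate when the null fixes a parameter at a boundary.
    """
    if df is None:
        if (null.model_id, alt.model_id) not in NESTED_PAIRS:
            raise LRTError(
                f"({null.model_id}, {alt.model_id}) is not a registered "
                f"nested pair; pass df= explicitly if it is nested")
        df = alt.n_params - null.n_params
    if df < 1:
        raise LRTError(
            f"alternative must have more free parameters than the null "
            f"(df={df})")
    stat = 2.0 * (alt.lnL - null.lnL)
    if stat < 0:
        warnings.warn(
            f"lnL({alt.model_id}) < lnL({null.model_id}); D clamped to 0 "
            f"(was {stat:.6g})", stacklevel=2)
        stat = 0.0
    p = float(chi2.sf(stat, df))
    if boundary_mixture and stat > 0:
        p = 0.5 * p
    return LRTResult(null.model_id, alt.model_id, stat, df, min(p, 1.0))


def compare_models(fits: Sequence[ModelFit],
                   pairs: Sequence[tuple[str, str]] | None = None,
                   alpha: float = 0.05,
                   boundary_mixture: bool = False) -> pd.DataFrame:
    """LRT table over nested model pairs, with Bonferroni-adjusted p-values.

    ``pairs`` defaults to every registered nested pair for which both fits
    are present. Columns: null, alt, D, df, p_raw, p_bonferroni, best_fit;
    the alternative is flagged best-fitting when the raw p-value beats
    ``alpha`` (the adjusted column is reported alongside for stricter
    readings).
    """
    if len(fits) < 2:
        raise LRTError("need at least two fitted models to compare")
    by_id = {f.model_id: f for f in fits}
    if pairs is None:
        pairs = [(n, a) for n, a in NESTED_PAIRS
                 if n in by_id and a in by_id]
        if not pairs:
            raise LRTError("no registered nested pair among the given fits")
    else:
        for n, a in pairs:
            if n not in by_id or a not in by_id:
                missing = [m for m in (n, a) if m not in by_id]
                raise LRTError("pair references absent fit(s): "
                               + ", ".join(missing))
    rows = []
    k = len(pairs)
    for n, a in pairs:
        res = lrt(by_id[n], by_id[a], boundary_mixture=boundary_mixture)
        rows.append({
            "null": n, "alt": a, "D": res.statistic, "df": res.df,
            "p_raw": res.p_value,
            "p_bonferroni": min(1.0, res.p_value * k),
            "best_fit": res.p_value < alpha,
        })
    return pd.DataFrame(rows,
                        columns=["null", "alt", "D", "df", "p_raw",
                                 "p_bonferroni", "best_fit"])


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_branch_omega(omega: float) -> str:
    """Display class of a branch dN/dS estimate.

    ``purifying`` below 0.2; ``relaxed`` on the closed interval [0.2, 1];
    ``positive`` above 1; ``saturated`` for an infinite estimate (dS ≈ 0).
    """
    if math.isnan(omega) or omega < 0:
        raise TreekitError(f"omega must be a non-negative real, got {omega}")
    if math.isinf(omega):
        return "saturated"
    if omega < 0.2:
        return "purifying"
    if omega <= 1.0:
        return "relaxed"
    return "positive"


def classify_site_significance(p_value: float) -> str:
    """Significance class of a per-site positive-selection p-value:
    ``strong`` below 0.01, ``moderate`` below 0.05, else ``ns``."""
    if math.isnan(p_value) or not 0.0 <= p_value <= 1.0:
        raise TreekitError(f"p-value outside [0, 1]: {p_value}")
    if p_value < 0.01:
        return "strong"
    if p_value < 0.05:
        return "moderate"
    return "ns"


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return repr(float(x))


def write_model_tsv(fit: ModelFit, path) -> None:
    """Serialize a fit to the three-section interchange TSV."""
    lines = [f"{_TSV_MAGIC}\t{_TSV_VERSION}",
             f"model_id\t{fit.model_id}",
             f"lnL\t{_fmt(fit.lnL)}",
             f"n_params\t{fit.n_params}",
             "#branches"]
    for bid in fit.branch_omegas:
        lines.append(f"{bid}\t{_fmt(fit.branch_omegas[bid])}")
    lines.append("#sites")
    for s in fit.sites:
        p = "NA" if s.p_value is None else _fmt(s.p_value)
        probs = "NA" if s.class_probabilities is None else \
            ",".join(_fmt(v) for v in s.class_probabilities)
        lines.append(f"{s.site_index}\t{_fmt(s.omega)}\t{p}\t{probs}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model_tsv(path) -> ModelFit:
    """Parse the three-section interchange TSV back into a :class:`ModelFit`.

    Header keys ``model_id``/``lnL``/``n_params`` are mandatory; the token
    ``inf`` maps to +infinity; site indices must be strictly increasing.
    Errors carry the offending line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_TSV_MAGIC):
        raise ModelTSVError(f"{path}: missing '{_TSV_MAGIC}' header", 1)
    header: dict[str, str] = {}
    branches: dict[str, float] = {}
    sites: list[SiteRecord] = []
    section = "header"
    last_site = 0
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        if line == "#branches":
            section = "branches"
            continue
        if line == "#sites":
            section = "sites"
            continue
        parts = line.split("\t")
        if section == "header":
            if len(parts) != 2:
                raise ModelTSVError("expected 'key<TAB>value' in header", ln)
            header[parts[0]] = parts[1]
        elif section == "branches":
            if len(parts) != 2:
                raise ModelTSVError(
                    "expected 'branch_id<TAB>omega' in branch block", ln)
            try:
                branches[parts[0]] = (math.inf if parts[1] == "inf"
                                      else float(parts[1]))
            except ValueError:
                raise ModelTSVError(f"bad omega {parts[1]!r}", ln) from None
        else:
            if len(parts) != 4:
                raise ModelTSVError(
                    "expected 4 tab-separated site columns", ln)
            try:
                idx = int(parts[0])
                omega = math.inf if parts[1] == "inf" else float(parts[1])
                p = None if parts[2] == "NA" else float(parts[2])
                probs = None if parts[3] == "NA" else tuple(
                    float(v) for v in parts[3].split(","))
            except ValueError as exc:
                raise ModelTSVError(f"bad site row: {exc}", ln) from None
            if idx <= last_site:
                raise ModelTSVError(
                    f"site indices must be strictly increasing "
                    f"({idx} after {last_site})", ln)
            last_site = idx
            try:
                sites.append(SiteRecord(idx, omega, p, probs))
            except TreekitError as exc:
                raise ModelTSVError(str(exc), ln) from None
    for key in ("model_id", "lnL", "n_params"):
        if key not in header:
            raise ModelTSVError(f"missing mandatory header key {key!r}")
    try:
        return ModelFit(header["model_id"], float(header["lnL"]),
                        int(header["n_params"]), branches, sites)
    except (ValueError, TreekitError) as exc:
        raise ModelTSVError(f"bad header values: {exc}") from None
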