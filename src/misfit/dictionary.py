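"""The ranked fine-tuner dictionary and forward-design panel selection.

Ranking all MRE variants by measured expression yields a "dictionary" of
miRNA silencing-mediated fine-tuners: a lookup from sequence identity to
relative expression output. Adjacent-rank step sizes quantify how finely
expression can be dialled; panel selection picks the variant closest to
each requested expression level; cross-context regressions test whether
variant strength transfers between transgenes or cell types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mre import parse_variant_id

__all__ = [
    "PanelSpec",
    "FitResult",
    "build_dictionary",
    "step_size_stats",
    "select_panel",
    "assemble_validation_panel",
    "cross_context_fit",
]


def _canonical_key(variant_id: str):
    """Deterministic tie-break: (positions, bases) lexicographic; controls last."""
    try:
        subs = sorted(parse_variant_id(variant_id))
    except ValueError:
        return ((math.inf,), (variant_id,))
    return (tuple(p for p, _ in subs), tuple(b for _, b in subs))


def _n_substitutions(variant_id: str) -> int | None:
    try:
        return len(parse_variant_id(variant_id))
    except ValueError:
        return None


def build_dictionary(
    expr: pd.DataFrame, subset: str = "singles", reference: str = "max"
) -> pd.DataFrame:
    """Rank variants by mean expression, rescaled to % of maximal expression.

    ``expr`` is an expression table indexed by variant_id with ``mean`` and
    ``sd`` columns (as produced by :func:`misfit.quantify.quantify_screen`).
    ``subset`` picks 'singles' (one substitution), 'doubles' (two) or 'all'
    (every canonical variant id, perfect included). ``reference`` sets what
    counts as 100%: the subset's own maximum mean ('max') or a named
    variant/control id. Ties in expression are broken by canonical variant
    order, so the ranking is stable across runs.

    Returns a DataFrame with columns rank, variant_id, expression_pct,
    sd_pct and attrs['reference_max'] holding the expression used as 100%.
    """
    if expr.empty:
        raise ValueError("expression table is empty")
    ks = expr.index.to_series().map(_n_substitutions)
    if subset == "singles":
        sel = expr[ks == 1]
    elif subset == "doubles":
        sel = expr[ks == 2]
    elif subset == "all":
        sel = expr[ks.notna()]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if sel.empty:
        raise ValueError(f"no variants in subset {subset!r}")

    if reference == "max":
        ref = float(sel["mean"].max())
    else:
        if reference not in expr.index:
            raise ValueError(f"reference variant {reference!r} not in table")
        ref = float(expr.loc[reference, "mean"])
    if not ref > 0:
        raise ValueError("reference expression must be positive")

    order = sorted(
        sel.index, key=lambda vid: (-sel.loc[vid, "mean"], _canonical_key(vid))
    )
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "variant_id": order,
            "expression_pct": [100.0 * sel.loc[v, "mean"] / ref for v in order],
            "sd_pct": [
                100.0 * sel.loc[v, "sd"] / ref if "sd" in sel.columns else np.nan
                for v in order
            ],
        }
    )
    out.attrs["reference_max"] = ref
    return out


def step_size_stats(dictionary: pd.DataFrame) -> tuple[float, float, float]:
    """(median, q25, q75) of expression differences between adjacent ranks.

    Differences are in % of maximal expression; quartiles use linear
    interpolation.
    """
    if len(dictionary) < 2:
        raise ValueError("need at least two dictionary records")
    diffs = -np.diff(np.asarray(dictionary["expression_pct"], dtype=float))
    if (diffs < -1e-9).any():
        raise ValueError("dictionary is not sorted by descending expression")
    med, q25, q75 = np.percentile(diffs, [50, 25, 75])
    return float(med), float(q25), float(q75)


def select_panel(
    dictionary: pd.DataFrame,
    targets: Sequence[float],
    unique: bool = False,
) -> list[str]:
    """For each target expression fraction, the nearest dictionary variant.

    Distance is |expression - target| on the 0-1 scale of the dictionary's
    reference maximum; ties go to the higher-expression variant, then to
    canonical variant order. With ``unique=True`` each variant is used at
    most once (targets processed in the given order).
    """
    if dictionary.empty:
        raise ValueError("dictionary is empty")
    if any(not 0 <= t <= 1 for t in targets):
        raise ValueError("targets must be expression fractions in [0, 1]")
    fracs = np.asarray(dictionary["expression_pct"], dtype=float) / 100.0
    vids = list(dictionary["variant_id"])
    taken: set[str] = set()
    chosen: list[str] = []
    for t in targets:
        best = None
        for vid, e in zip(vids, fracs):
            if unique and vid in taken:
                continue
            key = (abs(e - t), -e, _canonical_key(vid))
            if best is None or key < best[0]:
                best = (key, vid)
        if best is None:
            raise ValueError("dictionary exhausted before all targets were assigned")
        chosen.append(best[1])
        taken.add(best[1])
    return chosen


@dataclass(frozen=True)
class PanelSpec:
    """A validation panel: member variants with roles, crossed with transgenes."""

    members: tuple[tuple[str, str], ...]  # (variant_id, role)
    transgenes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [vid for vid, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("panel member ids must be unique")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_constructs(self) -> int:
        return len(self.members) * len(self.transgenes)


#: fixed controls appended to every validation panel
_PANEL_CONTROLS = (
    ("cel-miR-67", "nontargeted_control"),
    ("perfect_1x", "perfect_1x"),
    ("perfect_2x", "perfect_2x"),
    ("perfect_4x", "perfect_4x"),
)


def assemble_validation_panel(
    random_variants: Sequence[str], transgenes: Sequence[str] = ()
) -> PanelSpec:
    """The screen-validation panel: 15 screen variants plus 4 controls.

    The 15 randomly drawn single/double variants are joined by a
    non-targeted control site and 1x/2x/4x perfectly complementary sites
    (19 members); crossing with the transgene list gives the construct
    count (3 transgenes -> 57 constructs).
    """
    if len(random_variants) != 15:
        raise ValueError(f"exactly 15 screen variants required, got {len(random_variants)}")
    members = tuple((vid, "random_single_or_double") for vid in random_variants)
    return PanelSpec(members=members + _PANEL_CONTROLS, transgenes=tuple(transgenes))


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def cross_context_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least squares of y on x with a t-test for slope != 0.

    Used to compare variant strength between expression contexts
    (e.g. screen read-out vs RT-qPCR, or one transgene vs another).
    A constant y gives slope 0 and R^2 = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    n = x.size
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("x has zero variance; slope is undefined")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    se = math.sqrt(ss_res / (n - 2) / sxx)
    if se == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        p = 2.0 * stats.t.sf(abs(slope) / se, df=n - 2)
    return FitResult(
        slope=float(slope),
        intercept=intercept,
        r_squared=float(r_squared),
        p_slope=float(p),
        n=n,
    )
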