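"""One-way ANOVA with Fisher's LSD and compact letter displays.

Treatment means in cohort studies are conventionally presented as
"mean±SE letter" cells: a one-way analysis of variance is followed by
unprotected pairwise least-significant-difference (LSD) t tests using
the pooled error mean square, and groups are labelled with letters so
that two groups share a letter exactly when their difference is not
significant at level α.  No multiplicity correction is applied beyond
the LSD convention itself.

Letters are assigned with the insert-and-absorb algorithm: start from a
single letter covering all groups; for every significant pair, split
each letter containing both; finally absorb letters whose group set is
contained in another's.  By construction a significant pair never
shares a letter and a non-significant pair always does.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass
class AnovaResult:
    labels: tuple[str, ...]
    means: dict[str, float]
    ns: dict[str, int]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    mse: float                 # pooled within-group mean square


@dataclass
class LetterDisplay:
    letters: dict[str, str]    # group -> sorted letter string, 'a' = largest mean
    alpha: float

    def shares_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical between/within decomposition; p from the F distribution.

    Requires at least two groups of at least two values each.  When the
    pooled within-group variance is zero, F is 0 with p = 1 if all
    means coincide, else infinite with p = 0.
    """
    if len(groups) < 2:
        raise DataError("ANOVA needs at least two groups")
    labels = tuple(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, v in arrays.items():
        if v.size < 2:
            raise DataError(f"group {g!r} has fewer than two values")
    N = sum(v.size for v in arrays.values())
    k = len(labels)
    grand = sum(v.sum() for v in arrays.values()) / N
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    dfb, dfw = k - 1, N - k
    mse = ssw / dfw
    if mse == 0:
        f = 0.0 if ssb == 0 else np.inf
        p = 1.0 if ssb == 0 else 0.0
    else:
        f = (ssb / dfb) / mse
        p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(
        labels=labels,
        means={g: float(v.mean()) for g, v in arrays.items()},
        ns={g: int(v.size) for g, v in arrays.items()},
        f_statistic=float(f),
        df_between=dfb,
        df_within=dfw,
        p_value=p,
        mse=float(mse),
    )


def lsd_pairwise_p(result: AnovaResult, a: str, b: str) -> float:
    """Two-sided p of the LSD t test for one pair, using pooled MSE."""
    se = np.sqrt(result.mse * (1 / result.ns[a] + 1 / result.ns[b]))
    diff = result.means[a] - result.means[b]
    if se == 0:
        return 1.0 if diff == 0 else 0.0
    t = diff / se
    return float(2 * stats.t.sf(abs(t), result.df_within))


def lsd_letters(result: AnovaResult, alpha: float = 0.05) -> LetterDisplay:
    """Compact letter display from pairwise LSD decisions at level α."""
    order = sorted(result.labels, key=lambda g: -result.means[g])
    significant = {
        frozenset((a, b))
        for a, b in itertools.combinations(order, 2)
        if lsd_pairwise_p(result, a, b) < alpha
    }
    # insert-and-absorb on sets of groups
    columns: list[set[str]] = [set(order)]
    for pair in significant:
        a, b = tuple(pair)
        next_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                next_cols.append(col - {a})
                next_cols.append(col - {b})
            else:
                next_cols.append(col)
        # absorb: drop empties, duplicates and columns contained in another
        uniq: list[set[str]] = []
        for c in next_cols:
            if c and c not in uniq:
                uniq.append(c)
        columns = [c for c in uniq if not any(c < d for d in uniq)]
    # letter order follows the highest-mean group each column contains
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = _letter_stream()
    letters: dict[str, list[str]] = {g: [] for g in order}
    for col, letter in zip(columns, alphabet):
        for g in col:
            letters[g].append(letter)
    return LetterDisplay(
        letters={g: "".join(sorted(v)) for g, v in letters.items()},
        alpha=alpha,
    )


def _letter_stream():
    yield from string.ascii_lowercase
    for a, b in itertools.product(string.ascii_lowercase, repeat=2):
        yield a + b


def format_mean_se_letter(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05, decimals: int = 2
) -> dict[str, str]:
    """Render each group as the conventional ``mean±SE letter`` cell."""
    result = one_way_anova(groups)
    display = lsd_letters(result, alpha=alpha)
    out = {}
    for g in result.labels:
        v = np.asarray(groups[g], dtype=float)
        se = v.std(ddof=1) / np.sqrt(v.size)
        out[g] = f"{v.mean():.{decimals}f}±{se:.{decimals}f}{display.letters[g]}"
    return out
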