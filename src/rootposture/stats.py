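"""Nonparametric group comparisons for posture and angle indices.

The omnibus test is the tie-corrected Kruskal-Wallis rank ANOVA.  All-
pairs post hoc comparisons use the asymptotic Steel-Dwass procedure:
each pair is ranked jointly (midranks), the standardized Wilcoxon-type
statistic is computed with the tie-corrected variance, and sqrt(2)|Z| is
referred to the studentized-range distribution with k groups and
infinite degrees of freedom.  Planned two-group contrasts use the
Brunner-Munzel test of the relative effect P(X<Y) + 0.5 P(X=Y) with the
small-sample t approximation (Satterthwaite degrees of freedom) and an
optional Bonferroni family correction.  Group letters follow the
insert-and-absorb compact-letter-display algorithm: two groups share a
letter iff they are not significantly different.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError


@dataclass
class BrunnerMunzelResult:
    statistic: float
    pvalue: float
    relative_effect: float
    df: float
    pvalue_bonferroni: float
    family_size: int
    degenerate: bool = False


@dataclass
class GroupComparison:
    index_name: str
    groups: list[str]
    omnibus_H: float
    omnibus_p: float
    pairwise_p: pd.DataFrame
    method: str
    correction: str
    family_size: int
    alpha: float
    letters: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "index_name": self.index_name,
            "groups": self.groups,
            "omnibus_H": self.omnibus_H,
            "omnibus_p": self.omnibus_p,
            "pairwise_p": self.pairwise_p.to_dict(),
            "method": self.method,
            "correction": self.correction,
            "family_size": self.family_size,
            "alpha": self.alpha,
            "letters": self.letters,
        }


def _check_groups(groups: list[np.ndarray], min_n: int = 1) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    out = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float).ravel()
        if a.size < min_n:
            raise ParameterError(f"group {i} has n={a.size} < {min_n}")
        out.append(a)
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value."""
    groups = _check_groups(groups, min_n=1)
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        H += g.size * (r.mean() - (N + 1) / 2.0) ** 2
        start += g.size
    H *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (N**3 - N)
    if denom == 0.0:  # every observation identical
        return 0.0, 1.0
    H /= denom
    p = float(sps.chi2.sf(H, len(groups) - 1))
    return float(H), p


def _pair_z(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized tie-corrected Wilcoxon statistic for one pair."""
    pooled = np.concatenate([a, b])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    W = float(ranks[a.size :].sum())
    E = b.size * (N + 1) / 2.0
    V = a.size * b.size / (N * (N - 1.0)) * (float((ranks**2).sum()) - N * (N + 1) ** 2 / 4.0)
    if V <= 0:
        return 0.0
    return (W - E) / np.sqrt(V)


def steel_dwass(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> pd.DataFrame:
    """Asymptotic Steel-Dwass all-pairs p-value matrix.

    For k = 2 this reduces to the two-sided tie-corrected normal
    approximation of the Wilcoxon rank-sum test.
    """
    groups = _check_groups(groups, min_n=2)
    k = len(groups)
    labels = labels if labels is not None else [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise ParameterError("labels length must match number of groups")
    P = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(_pair_z(groups[i], groups[j]))
            p = float(sps.studentized_range.sf(z * np.sqrt(2.0), k, np.inf))
            P[i, j] = P[j, i] = min(1.0, p)
    return pd.DataFrame(P, index=labels, columns=labels)


def brunner_munzel(
    a: np.ndarray, b: np.ndarray, correction_family_size: int = 1
) -> BrunnerMunzelResult:
    """Brunner-Munzel test of the relative effect P(X<Y) + 0.5 P(X=Y).

    Uses midranks and the t approximation with Satterthwaite-type
    degrees of freedom.  When both samples are internally constant the
    variance degenerates; the result is flagged and p = 1.
    """
    if correction_family_size < 1:
        raise ParameterError("correction_family_size must be >= 1")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ParameterError("both samples need n >= 2")
    N = na + nb
    pooled = np.concatenate([a, b])
    R = sps.rankdata(pooled)
    Ra, Rb = R[:na], R[na:]
    ra_int = sps.rankdata(a)
    rb_int = sps.rankdata(b)
    Ra_mean, Rb_mean = Ra.mean(), Rb.mean()
    p_hat = (Rb_mean - (nb + 1) / 2.0) / na
    Sa2 = np.sum((Ra - ra_int - Ra_mean + (na + 1) / 2.0) ** 2) / (na - 1)
    Sb2 = np.sum((Rb - rb_int - Rb_mean + (nb + 1) / 2.0) ** 2) / (nb - 1)
    sig = na * Sa2 + nb * Sb2
    if sig <= 0:
        # Degenerate rank variance: either every pooled value is tied
        # (relative effect 1/2, no evidence -> p = 1) or the samples are
        # completely separated (relative effect 0 or 1 -> p -> 0).
        separated = not np.isclose(p_hat, 0.5)
        return BrunnerMunzelResult(
            statistic=float(np.inf * np.sign(p_hat - 0.5)) if separated else 0.0,
            pvalue=0.0 if separated else 1.0,
            relative_effect=float(p_hat),
            df=float("nan"),
            pvalue_bonferroni=0.0 if separated else 1.0,
            family_size=correction_family_size,
            degenerate=True,
        )
    stat = float(na * nb * (Rb_mean - Ra_mean) / (N * np.sqrt(sig)))
    df = float(sig**2 / ((na * Sa2) ** 2 / (na - 1) + (nb * Sb2) ** 2 / (nb - 1)))
    p = float(2.0 * sps.t.sf(abs(stat), df))
    return BrunnerMunzelResult(
        statistic=stat,
        pvalue=p,
        relative_effect=float(p_hat),
        df=df,
        pvalue_bonferroni=min(1.0, p * correction_family_size),
        family_size=correction_family_size,
    )


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    return alpha / m


def compact_letters(
    pairwise_p: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    labels: list[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise p-value is >= alpha
    (not significantly different).  NaN p-values (diagonal) are ignored.
    """
    if isinstance(pairwise_p, pd.DataFrame):
        labels = list(pairwise_p.index) if labels is None else labels
        P = pairwise_p.to_numpy(dtype=float)
    else:
        P = np.asarray(pairwise_p, dtype=float)
        labels = labels if labels is not None else [f"g{i}" for i in range(P.shape[0])]
    k = P.shape[0]
    if P.shape != (k, k):
        raise ParameterError("pairwise_p must be square")
    # letter groups as sets of group indices; start with one all-inclusive set
    sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            p = P[i, j]
            if np.isnan(p) or p >= alpha:
                continue
            new_sets: list[set[int]] = []
            for s in sets:
                if i in s and j in s:
                    new_sets.append(s - {i})
                    new_sets.append(s - {j})
                else:
                    new_sets.append(s)
            # absorb sets contained in another
            sets = [
                s
                for idx, s in enumerate(new_sets)
                if s
                and not any(
                    s < t or (s == t and idx2 < idx)
                    for idx2, t in enumerate(new_sets)
                    if idx2 != idx
                )
            ]
    # order letter sets by their first (smallest) member for stable output
    sets.sort(key=lambda s: min(s))
    alphabet = string.ascii_lowercase
    out = {lab: "" for lab in labels}
    for letter_idx, s in enumerate(sets):
        letter = (
            alphabet[letter_idx]
            if letter_idx < 26
            else alphabet[letter_idx // 26 - 1] + alphabet[letter_idx % 26]
        )
        for gi in sorted(s):
            out[labels[gi]] += letter
    return out


def compare_groups(
    df: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    method: str = "steel_dwass",
    alpha: float = 0.05,
    family_size: int = 1,
) -> GroupComparison:
    """Omnibus + pairwise comparison of one index across groups.

    ``method`` is ``"steel_dwass"`` (all pairs, studentized range) or
    ``"brunner_munzel"`` (all pairs, each Bonferroni-corrected by
    ``family_size``; ``family_size=0`` means the number of pairs).
    """
    if value_col not in df.columns or group_col not in df.columns:
        raise ParameterError(f"missing column {value_col!r} or {group_col!r}")
    sub = df[[group_col, value_col]].dropna()
    labels = list(dict.fromkeys(sub[group_col]))
    groups = [sub.loc[sub[group_col] == g, value_col].to_numpy(float) for g in labels]
    H, omnibus_p = kruskal_wallis(groups)
    k = len(labels)
    if method == "steel_dwass":
        pw = steel_dwass(groups, labels)
        correction = "none"
        fam = family_size
    elif method == "brunner_munzel":
        fam = family_size if family_size >= 1 else k * (k - 1) // 2
        P = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                res = brunner_munzel(groups[i], groups[j], fam)
                P[i, j] = P[j, i] = res.pvalue_bonferroni
        pw = pd.DataFrame(P, index=labels, columns=labels)
        correction = "bonferroni"
    else:
        raise ParameterError("method must be 'steel_dwass' or 'brunner_munzel'")
    letters = compact_letters(pw, alpha=alpha)
    return GroupComparison(
        index_name=value_col,
        groups=labels,
        omnibus_H=H,
        omnibus_p=omnibus_p,
        pairwise_p=pw,
        method=method,
        correction=correction,
        family_size=fam,
        alpha=alpha,
        letters=letters,
    )
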