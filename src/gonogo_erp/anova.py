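"""Repeated-measures / mixed factorial ANOVA on balanced designs.

Classical univariate sums-of-squares decomposition with subject as an
additive random blocking factor (nested in the between-subject group when
one is present).  Every within-subject effect is tested against its own
effect-by-subject interaction; the between effect is tested against
subjects-within-groups.  With two-level factors every numerator df is 1,
so no sphericity correction arises.

The implementation computes each term by the Möbius (inclusion-exclusion)
formula on marginal cell means, which is exact for balanced data with one
observation per subject x within-cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    """Per-effect F table; ``table`` columns: effect, F, df_num, df_den, p,
    ss_effect, ss_error."""

    table: pd.DataFrame
    within: list[str]
    between: str | None
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"effect {name!r} not in {list(self.table['effect'])}")
        return hit.iloc[0]

    def __repr__(self) -> str:
        lines = [f"AnovaResult(n={self.n_subjects})"]
        for r in self.table.itertuples():
            lines.append(
                f"  {r.effect}: F({r.df_num:.0f},{r.df_den:.0f}) = {r.F:.3f},"
                f" p = {r.p:.4g}"
            )
        return "\n".join(lines)


def _subsets(items: tuple) -> list[tuple]:
    return list(chain.from_iterable(
        combinations(items, k) for k in range(len(items) + 1)))


def _check_balanced(df: pd.DataFrame, within: list[str], subject: str) -> None:
    counts = df.groupby([subject] + within, observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(
            "design is unbalanced: expected exactly one observation per "
            f"subject x within-cell, offending cells:\n{bad.head(10)}"
        )
    per_subject = df.groupby(subject, observed=True).size()
    if per_subject.nunique() != 1:
        raise ValueError("design is unbalanced: subjects have unequal "
                         "numbers of cells")


def rm_anova(
    table: pd.DataFrame,
    within: list[str],
    between: str | None = None,
    value: str = "value",
    subject: str = "subject",
) -> AnovaResult:
    """Balanced repeated-measures (optionally mixed) factorial ANOVA.

    ``table`` is long-format with one row per subject x within-cell.
    ``within`` lists within-subject factor columns; ``between`` optionally
    names a between-subject grouping column (constant per subject).
    """
    df = table.copy()
    if df.empty:
        raise ValueError("empty table")
    for col in [subject, value] + within + ([between] if between else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from table")
    _check_balanced(df, within, subject)

    subjects = df[subject].unique()
    n_subj = len(subjects)
    if between is not None:
        gmap = df.groupby(subject, observed=True)[between].nunique()
        if (gmap != 1).any():
            raise ValueError("between-subject factor varies within a subject")
        groups = df.groupby(subject, observed=True)[between].first()
        group_sizes = groups.value_counts()
        if (group_sizes < 2).any():
            raise ValueError("every between-group level needs >= 2 subjects")
        n_groups = len(group_sizes)
        if group_sizes.nunique() != 1:
            # unequal group sizes are fine for the Möbius formula only if
            # weighting is handled; use unweighted (type-II-like) means
            pass
    else:
        n_groups = 1

    y = df[value].to_numpy(float)
    N = len(y)
    grand = y.mean()

    levels = {f: sorted(df[f].unique()) for f in within}
    for f, lv in levels.items():
        if len(lv) < 2:
            raise ValueError(f"within factor {f!r} has a single level")

    # marginal means over every subset of factors (within +- between)
    factors = list(within) + ([between] if between else [])

    def marginal_mean(sub: tuple):
        if not sub:
            return grand
        return df.groupby(list(sub), observed=True)[value].mean()

    marg = {sub: marginal_mean(sub) for sub in _subsets(tuple(factors))}

    def effect_ss(eff: tuple) -> tuple[float, float]:
        """(SS, df) of a fixed effect by inclusion-exclusion on means."""
        cells = marg[eff].index
        tau = None
        for sub in _subsets(eff):
            sign = (-1) ** (len(eff) - len(sub))
            if not sub:
                term = pd.Series(grand, index=cells)
            else:
                m = marg[sub]
                if len(sub) == 1:
                    key = cells.get_level_values(sub[0]) if hasattr(
                        cells, "get_level_values") else cells
                    term = pd.Series(m.reindex(key).to_numpy(), index=cells)
                else:
                    idx = pd.MultiIndex.from_arrays(
                        [cells.get_level_values(f) for f in sub], names=sub)
                    term = pd.Series(m.reindex(idx).to_numpy(), index=cells)
            tau = term * sign if tau is None else tau + sign * term
        # proportional cell frequencies (balanced within, possibly unequal
        # groups): weight each cell by its actual observation count
        n_cell = df.groupby(list(eff), observed=True)[value].size().reindex(cells)
        ss = float((n_cell * tau**2).sum())
        dfree = 1.0
        for f in eff:
            dfree *= len(df[f].unique()) - 1
        return ss, dfree

    # subject means (per within-cell) for error terms
    cells_per_subject = int(N / n_subj)
    subj_group = df.groupby(subject, observed=True)[value].mean()
    if between is not None:
        group_of = df.groupby(subject, observed=True)[between].first()
        group_mean = df.groupby(between, observed=True)[value].mean()
        dev = subj_group - group_of.map(group_mean)
    else:
        dev = subj_group - grand
    ss_subj = float(cells_per_subject * (dev**2).sum())
    df_subj = n_subj - n_groups

    def error_ss(eff_w: tuple) -> tuple[float, float]:
        """(SS, df) of the eff_w x subject(within groups) interaction."""
        # per-subject marginal means over the within subset
        tau = None
        cols = list(eff_w)
        subj_marg = df.groupby([subject] + cols, observed=True)[value].mean()
        cells = subj_marg.index
        for sub in _subsets(eff_w):
            for with_subj in (True, False):
                sign_len = len(eff_w) + 1 - len(sub) - (1 if with_subj else 0)
                sign = (-1) ** sign_len
                if with_subj:
                    if not sub:
                        m = subj_group
                        key = cells.get_level_values(subject)
                        term = pd.Series(m.reindex(key).to_numpy(), index=cells)
                    else:
                        grouper = [subject] + list(sub)
                        m = df.groupby(grouper, observed=True)[value].mean()
                        idx = pd.MultiIndex.from_arrays(
                            [cells.get_level_values(f) for f in grouper],
                            names=grouper)
                        term = pd.Series(m.reindex(idx).to_numpy(), index=cells)
                else:
                    grouper = ([between] if between else []) + list(sub)
                    if not grouper:
                        term = pd.Series(grand, index=cells)
                    else:
                        m = df.groupby(grouper, observed=True)[value].mean()
                        if between:
                            keys = [cells.get_level_values(subject).map(group_of)
                                    if f == between else cells.get_level_values(f)
                                    for f in grouper]
                        else:
                            keys = [cells.get_level_values(f) for f in grouper]
                        if len(grouper) == 1:
                            term = pd.Series(
                                m.reindex(keys[0]).to_numpy(), index=cells)
                        else:
                            idx = pd.MultiIndex.from_arrays(keys, names=grouper)
                            term = pd.Series(m.reindex(idx).to_numpy(), index=cells)
                tau = sign * term if tau is None else tau + sign * term
        n_per = N / len(cells)
        ss = float(n_per * (tau**2).sum())
        dfree = float(df_subj)
        for f in eff_w:
            dfree *= len(df[f].unique()) - 1
        return ss, dfree

    rows = []
    within_t = tuple(within)
    effects = [e for e in _subsets(tuple(factors)) if e]
    error_cache: dict[tuple, tuple[float, float]] = {}
    for eff in effects:
        ss_e, df_e = effect_ss(eff)
        eff_w = tuple(f for f in eff if f in within_t)
        if eff_w:
            if eff_w not in error_cache:
                error_cache[eff_w] = error_ss(eff_w)
            ss_err, df_err = error_cache[eff_w]
        else:
            ss_err, df_err = ss_subj, df_subj
        F = (ss_e / df_e) / (ss_err / df_err) if ss_err > 0 else np.inf
        p = float(sps.f.sf(F, df_e, df_err))
        rows.append({
            "effect": " x ".join(eff), "F": F, "df_num": df_e,
            "df_den": df_err, "p": p, "ss_effect": ss_e, "ss_error": ss_err,
        })
    out = pd.DataFrame(rows)
    return AnovaResult(table=out, within=list(within), between=between,
                       n_subjects=n_subj)


def total_ss(table: pd.DataFrame, value: str = "value") -> float:
    y = table[value].to_numpy(float)
    return float(((y - y.mean()) ** 2).sum())


def simple_effects(
    table: pd.DataFrame,
    split_by: str,
    within: list[str],
    value: str = "value",
    subject: str = "subject",
) -> dict[str, AnovaResult]:
    """Within-level follow-up: rm_anova run separately per level of
    ``split_by`` (typically the between-subject factor)."""
    if split_by not in table.columns:
        raise ValueError(f"column {split_by!r} missing from table")
    out = {}
    for lev, sub in table.groupby(split_by, observed=True):
        out[lev] = rm_anova(sub, within=within, value=value, subject=subject)
    return out
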