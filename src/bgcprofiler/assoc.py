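"""Prevalence and presence/absence association analysis across sample groups.

After per-sample prediction, downstream questions are population-level: in
what proportion of samples from each group (body site, case vs control) is a
given BGC predicted, and is its presence associated with group membership?
Association uses the two-sided Fisher's exact test on the 2x2
present/absent x group table, with the conventional point-probability rule
(sum the probabilities of all margin-fixed tables no more probable than the
observed one).  Raw p-values are reported with significance tiers
(ns >= 0.05 > * >= 0.01 > ** >= 0.001 > ***); an optional
Benjamini-Hochberg correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats as sps


class AssociationError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """Boolean samples x BGCs matrix with a group label per sample."""

    presence: pd.DataFrame  # index: sample ids, columns: bgc ids, dtype bool
    groups: dict[str, str]  # sample -> group label

    def __post_init__(self):
        missing = [s for s in self.presence.index if s not in self.groups]
        if missing:
            raise AssociationError(f"samples missing from group map: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.presence.index)

    @property
    def bgc_ids(self) -> list[str]:
        return list(self.presence.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.presence.index if self.groups[s] == group]


def build_presence_matrix(
    report_paths: Sequence[str | Path], group_map: dict[str, str] | str | Path
) -> PresenceMatrix:
    """Assemble the presence matrix from per-sample prediction report TSVs.

    Samples with zero confirmed BGCs keep an all-false row (they still count
    in prevalence denominators).  Duplicate sample ids across reports and
    samples absent from the group map are errors.
    """
    if not isinstance(group_map, dict):
        df = pd.read_csv(group_map, sep="\t", header=None, names=["sample_id", "group"], comment="#")
        group_map = dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))

    presence: dict[str, set[str]] = {}
    for path in report_paths:
        rep = pd.read_csv(path, sep="\t")
        for sid in rep["sample_id"].astype(str).unique():
            if sid in presence:
                raise AssociationError(f"duplicate sample id across reports: {sid}")
            sub = rep[rep["sample_id"].astype(str) == sid]
            confirmed = sub[sub["confirmed"].astype(bool)]["bgc_id"].astype(str)
            presence[sid] = set(confirmed)

    missing = sorted(s for s in presence if s not in group_map)
    if missing:
        raise AssociationError(f"samples missing from group file: {missing}")

    all_bgcs = sorted(set().union(*presence.values())) if presence else []
    mat = pd.DataFrame(
        [[b in presence[s] for b in all_bgcs] for s in sorted(presence)],
        index=sorted(presence),
        columns=all_bgcs,
        dtype=bool,
    )
    return PresenceMatrix(presence=mat, groups={s: group_map[s] for s in mat.index})


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AssociationResult:
    bgc_id: str
    group_a: str
    group_b: str
    counts: tuple[tuple[int, int], tuple[int, int]]  # [[present_a, present_b], [absent_a, absent_b]]
    proportion_a: float
    proportion_b: float
    p_value: float

    @property
    def significance_tier(self) -> str:
        return significance_tier(self.p_value)


def fisher_association(
    matrix: PresenceMatrix, bgc_id: str, group_a: str, group_b: str
) -> AssociationResult:
    """Two-sided Fisher's exact test of BGC presence between two groups."""
    if bgc_id not in matrix.presence.columns:
        raise AssociationError(f"BGC {bgc_id} absent from presence matrix")
    col = matrix.presence[bgc_id]
    sa, sb = matrix.group_samples(group_a), matrix.group_samples(group_b)
    if not sa or not sb:
        raise AssociationError(f"empty group: {group_a if not sa else group_b}")
    pa, na = int(col[sa].sum()), len(sa)
    pb, nb = int(col[sb].sum()), len(sb)
    table = [[pa, pb], [na - pa, nb - pb]]
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return AssociationResult(
        bgc_id=bgc_id,
        group_a=group_a,
        group_b=group_b,
        counts=((pa, pb), (na - pa, nb - pb)),
        proportion_a=pa / na,
        proportion_b=pb / nb,
        p_value=p,
    )


def one_vs_rest_associations(
    matrix: PresenceMatrix, bh_correction: bool = False
) -> pd.DataFrame:
    """Per-BGC, per-group one-vs-rest Fisher tests over the whole matrix.

    Each group is contrasted against all remaining samples pooled.  With
    ``bh_correction`` a Benjamini-Hochberg q-value column is added; raw
    p-values with tier symbols remain the default report.
    """
    groups = sorted(set(matrix.groups.values()))
    rows = []
    for bgc_id in matrix.bgc_ids:
        col = matrix.presence[bgc_id]
        for g in groups:
            in_g = [s for s in matrix.samples if matrix.groups[s] == g]
            out_g = [s for s in matrix.samples if matrix.groups[s] != g]
            if not out_g:
                continue
            pa, na = int(col[in_g].sum()), len(in_g)
            pb, nb = int(col[out_g].sum()), len(out_g)
            p = float(
                sps.fisher_exact([[pa, pb], [na - pa, nb - pb]], alternative="two-sided")[1]
            )
            rows.append(
                {
                    "bgc_id": bgc_id,
                    "group": g,
                    "n_present_in_group": pa,
                    "n_group": na,
                    "n_present_rest": pb,
                    "n_rest": nb,
                    "proportion_group": pa / na,
                    "proportion_rest": pb / nb,
                    "p_value": p,
                    "tier": significance_tier(p),
                }
            )
    out = pd.DataFrame(rows)
    if bh_correction and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def prevalence_by_group(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-group, per-BGC prevalence: counts, fraction, one-decimal percent."""
    if not matrix.samples:
        raise AssociationError("empty presence matrix")
    groups = sorted(set(matrix.groups.values()))
    rows = []
    for g in groups:
        samples = matrix.group_samples(g)
        for bgc_id in matrix.bgc_ids:
            n_present = int(matrix.presence.loc[samples, bgc_id].sum())
            rows.append(
                {
                    "group": g,
                    "bgc_id": bgc_id,
                    "n_present": n_present,
                    "n_total": len(samples),
                    "proportion": n_present / len(samples),
                    "percent": round(100.0 * n_present / len(samples), 1),
                }
            )
    return pd.DataFrame(rows)
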