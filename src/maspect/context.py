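"""Trinucleotide-context relative mutation rates and CpG spectrum tests.

Every analyzable site belongs to one of 32 strand-collapsed trinucleotide
classes.  A class's relative rate is its per-site SNM rate divided by the
genome-wide per-site rate, so the site-weighted mean over all classes is 1
by construction.  Because G:C base pairs mutate faster than A:T overall,
class-level significance is judged against the genome-wide rate of the
class's own center base pair (the 16 A:T-center and 16 G:C-center classes
are tested separately), with a one-sample t over per-line relative rates and
a Bonferroni-corrected threshold of 0.05/16 = 0.003125.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    AT_CENTER_CLASSES,
    GC_CENTER_CLASSES,
    TRINUC_CLASSES,
    TRINUC_CLASS_LABELS,
    TrinucleotideCensus,
)
from .rates import ExperimentDesign

__all__ = [
    "ContextRateTable",
    "CpGSummary",
    "context_relative_rates",
    "context_significance",
    "cpg_spectrum_test",
    "class_direction_test",
    "bonferroni_threshold",
    "cpg_direction_counts",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def bonferroni_threshold(n_tests: int = 16, alpha: float = 0.05) -> float:
    return alpha / n_tests


@dataclass
class ContextRateTable:
    """Per-class counts, relative rates, and the per-line count matrix."""

    table: pd.DataFrame  # index: class representative
    per_line_counts: pd.DataFrame  # lines x 32 classes
    census: TrinucleotideCensus
    design: ExperimentDesign

    @property
    def site_weighted_mean(self) -> float:
        t = self.table
        usable = t["sites"] > 0
        return float(
            (t.loc[usable, "relative_rate"] * t.loc[usable, "sites"]).sum()
            / t.loc[usable, "sites"].sum()
        )


def _context_counts(events, line_ids) -> pd.DataFrame:
    """Per-line x per-class SNM counts (lone SNM events with known context)."""
    idx = {rep: i for i, rep in enumerate(TRINUC_CLASSES)}
    mat = pd.DataFrame(
        0, index=list(line_ids), columns=list(TRINUC_CLASSES), dtype=int
    )
    for e in events:
        if e.event_class != "SNM":
            continue
        for ctx in e.contexts:
            if ctx is not None and ctx in idx:
                mat.loc[e.line_id, ctx] += 1
    return mat


def context_relative_rates(
    events, census: TrinucleotideCensus, design: ExperimentDesign,
    line_ids=None,
) -> ContextRateTable:
    """Relative rate per trinucleotide class vs the genome-wide per-site rate.

    The genome-wide rate here uses context-assignable counts over
    context-assignable sites so the site-weighted mean relative rate is
    exactly 1.
    """
    if line_ids is None:
        line_ids = sorted({e.line_id for e in events})
    per_line = _context_counts(events, line_ids)
    counts = per_line.sum(axis=0)
    sites = pd.Series(census.class_sites)
    total_gen = design.total_generations
    overall = counts.sum() / (sites.sum() * total_gen)
    rate = counts / (sites * total_gen)
    rel = rate / overall if overall > 0 else rate * float("nan")
    table = pd.DataFrame(
        {
            "label": TRINUC_CLASS_LABELS,
            "center": [r[1] for r in TRINUC_CLASSES],
            "sites": sites.astype(int),
            "count": counts,
            "rate": rate,
            "relative_rate": rel,
        },
        index=list(TRINUC_CLASSES),
    )
    return ContextRateTable(
        table=table, per_line_counts=per_line, census=census, design=design
    )


def context_significance(
    ctx: ContextRateTable, base_set: str, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sample t-tests of per-line relative rates against 1 per class.

    ``base_set`` is 'AT' or 'GC'; each class is normalized by the pooled
    per-site rate of its own base set, honoring the separate analysis of
    A:T-center and G:C-center classes.  Zero-variance classes get NaN p and
    are flagged unusable.

    The test is one-sided for elevation (hypermutable contexts).  With
    per-line class counts this sparse the t approximation is sound in the
    elevation direction but badly anti-conservative for deficits — a class
    with a handful of expected events and zero observed yields a tiny
    artificial variance — so a two-sided flag would be dominated by deficit
    artifacts.
    """
    if base_set not in ("AT", "GC"):
        raise ValueError("base_set must be 'AT' or 'GC'")
    cls_idx = AT_CENTER_CLASSES if base_set == "AT" else GC_CENTER_CLASSES
    classes = [TRINUC_CLASSES[i] for i in cls_idx]
    sites = ctx.table.loc[classes, "sites"].astype(float)
    counts = ctx.per_line_counts[classes]
    n_lines = len(counts)
    if n_lines < 2:
        raise ValueError("need at least 2 lines for across-line t-tests")
    g = ctx.design.generations
    base_rate = ctx.table.loc[classes, "count"].sum() / (
        sites.sum() * ctx.design.total_generations
    )
    threshold = bonferroni_threshold(len(classes), alpha)
    rows = []
    for cls in classes:
        if sites[cls] <= 0 or base_rate <= 0:
            rows.append({"class": cls, "t": np.nan, "p": np.nan,
                         "mean_relative_rate": np.nan, "significant": False,
                         "flag": "no-sites"})
            continue
        per_line_rel = counts[cls].to_numpy(float) / (sites[cls] * g) / base_rate
        mean = per_line_rel.mean()
        sd = per_line_rel.std(ddof=1)
        if sd == 0:
            rows.append({"class": cls, "t": np.nan, "p": np.nan,
                         "mean_relative_rate": mean, "significant": False,
                         "flag": "zero-variance"})
            continue
        t = (mean - 1.0) / (sd / math.sqrt(n_lines))
        p = float(stats.t.sf(t, n_lines - 1))  # one-sided: elevation
        rows.append({"class": cls, "t": t, "p": p,
                     "mean_relative_rate": mean,
                     "significant": bool(p <= threshold), "flag": ""})
    out = pd.DataFrame(rows).set_index("class")
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["base_set"] = base_set
    return out


# ----------------------------------------------------------------------------
# CpG and per-class direction tests
# ----------------------------------------------------------------------------

CPG_DIRECTIONS = ["C>A", "C>T", "C>G"]


def cpg_direction_counts(events) -> dict[str, int]:
    """Directional counts at CpG-flagged SNM sites, pyrimidine-strand oriented."""
    counts = {d: 0 for d in CPG_DIRECTIONS}
    for e in events:
        if e.event_class != "SNM":
            continue
        for (ref, alt), flag in zip(e.snm_changes, e.cpg_flags):
            if not flag:
                continue
            if ref == "C":
                counts[f"C>{alt}"] += 1
            elif ref == "G":
                counts[f"C>{_COMP[alt]}"] += 1
    return counts


def _multinomial_exact_p(observed, probs) -> float:
    """Exact multinomial test: total probability of outcomes as or less
    probable than the observed one."""
    observed = tuple(int(x) for x in observed)
    n = sum(observed)
    probs = np.asarray(probs, dtype=float)
    p_obs = stats.multinomial.pmf(observed, n, probs)
    total = 0.0
    k = len(observed)
    for combo in itertools.product(range(n + 1), repeat=k - 1):
        if sum(combo) > n:
            continue
        outcome = combo + (n - sum(combo),)
        p = stats.multinomial.pmf(outcome, n, probs)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(float(total), 1.0)


@dataclass
class CpGSummary:
    counts: dict[str, int]
    expected_proportions: dict[str, float]
    chi2: float
    p: float
    test: str = "chi2"

    @property
    def proportions(self) -> dict[str, float]:
        n = sum(self.counts.values())
        return {k: v / n for k, v in self.counts.items()}


def cpg_spectrum_test(cpg_counts: dict, expected_proportions: dict) -> CpGSummary:
    """Chi-square of CpG directional counts vs the genome-wide C:G spectrum.

    ``expected_proportions`` are the genome-wide proportions of C>A, C>T and
    C>G among C:G-source SNMs.  Falls back to an exact multinomial test when
    any expected cell is below 1.
    """
    obs = np.array([cpg_counts[d] for d in CPG_DIRECTIONS], dtype=float)
    if obs.sum() < 1:
        raise ValueError("need at least one CpG mutation")
    probs = np.array([expected_proportions[d] for d in CPG_DIRECTIONS], dtype=float)
    probs = probs / probs.sum()
    expected = probs * obs.sum()
    if (expected < 1).any():
        p = _multinomial_exact_p(obs, probs)
        chi2 = float(((obs - expected) ** 2 / np.where(expected > 0, expected, 1)).sum())
        test = "multinomial-exact"
    else:
        chi2, p = stats.chisquare(obs, expected)
        chi2, p, test = float(chi2), float(p), "chi2"
    return CpGSummary(
        counts={d: int(c) for d, c in zip(CPG_DIRECTIONS, obs)},
        expected_proportions={d: float(q) for d, q in zip(CPG_DIRECTIONS, probs)},
        chi2=chi2,
        p=p,
        test=test,
    )


def class_direction_test(observed_counts, expected_proportions):
    """Chi-square (df=2) of one class's direction counts vs expectation.

    ``observed_counts`` and ``expected_proportions`` are aligned sequences
    over the three alternative bases.  Uses the exact multinomial test when
    the total count is below 5.
    """
    obs = np.asarray(observed_counts, dtype=float)
    probs = np.asarray(expected_proportions, dtype=float)
    probs = probs / probs.sum()
    expected = probs * obs.sum()
    chi2 = float(((obs - expected) ** 2 / np.where(expected > 0, expected, 1)).sum())
    if obs.sum() < 5:
        return {"chi2": chi2, "p": _multinomial_exact_p(obs, probs),
                "expected": expected, "test": "multinomial-exact"}
    stat, p = stats.chisquare(obs, expected)
    return {"chi2": float(stat), "p": float(p), "expected": expected, "test": "chi2"}
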