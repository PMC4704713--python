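"""Per-base-per-generation mutation rates, spectra, and count-distribution fits.

Rates are events per site-generation: the denominator is
``n_lines x generations x L`` with L the reference length.  Standard errors
come from the variance of per-line rates across MA lines, the natural
uncertainty for a design where each line is an independent replicate of the
mutational process.

The conditional (per-site) spectrum divides each of the six strand-collapsed
substitution classes by the genomic abundance of its source base pair, so a
G/C-source class is per G/C site.  From these come the transition/transversion
ratio, the directional fold biases, and the mutational-equilibrium G/C
content u/(u+v).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ExperimentDesign",
    "RateEstimate",
    "SpectrumTable",
    "DistributionFit",
    "SNM_CLASSES",
    "snm_class_of",
    "class_rate",
    "conditional_spectrum",
    "ts_tv",
    "equilibrium_gc",
    "effective_population_size",
    "divergence_generations",
    "fit_count_distribution",
    "relative_likelihood",
]

#: the six strand-collapsed single-nucleotide change classes
SNM_CLASSES = [
    "GC>AT_ts",
    "AT>GC_ts",
    "GC>TA_tv",
    "AT>CG_tv",
    "GC>CG_tv",
    "AT>TA_tv",
]

_CHANGE_CLASS = {
    ("C", "T"): "GC>AT_ts", ("G", "A"): "GC>AT_ts",
    ("A", "G"): "AT>GC_ts", ("T", "C"): "AT>GC_ts",
    ("C", "A"): "GC>TA_tv", ("G", "T"): "GC>TA_tv",
    ("A", "C"): "AT>CG_tv", ("T", "G"): "AT>CG_tv",
    ("C", "G"): "GC>CG_tv", ("G", "C"): "GC>CG_tv",
    ("A", "T"): "AT>TA_tv", ("T", "A"): "AT>TA_tv",
}

TRANSITIONS = ("GC>AT_ts", "AT>GC_ts")
TRANSVERSIONS = ("GC>TA_tv", "AT>CG_tv", "GC>CG_tv", "AT>TA_tv")


def snm_class_of(ref: str, alt: str) -> str:
    """Map an (ref, alt) base substitution to its strand-collapsed class."""
    return _CHANGE_CLASS[(ref.upper(), alt.upper())]


@dataclass
class ExperimentDesign:
    """MA experiment bookkeeping: lines, generations, and genome length."""

    n_lines: int
    generations: float  # per-line cell generations G
    analyzed_length_bp: float  # L, the rate denominator length
    per_line_generations: dict[str, float] | None = None

    def __post_init__(self):
        if self.n_lines < 1 or self.generations <= 0 or self.analyzed_length_bp <= 0:
            raise ValueError("n_lines, generations and length must be positive")

    def generations_of(self, line_id) -> float:
        if self.per_line_generations:
            return self.per_line_generations.get(line_id, self.generations)
        return self.generations

    @property
    def total_generations(self) -> float:
        """Sum of per-line generations (n_lines x G when uniform)."""
        if self.per_line_generations:
            return float(sum(self.per_line_generations.values()))
        return self.n_lines * self.generations

    @property
    def site_generations(self) -> float:
        return self.total_generations * self.analyzed_length_bp


@dataclass
class RateEstimate:
    event_class: str
    count: int
    rate: float
    se: float
    site_generations: float
    per_line_rates: np.ndarray

    def __str__(self):
        return (
            f"{self.event_class}: {self.rate:.3g} +/- {self.se:.2g} "
            f"per base per generation ({self.count} events)"
        )


def class_rate(count: int, design: ExperimentDesign, per_line_counts=None,
               event_class: str = "SNM") -> RateEstimate:
    """Point rate and across-line SE for one mutation class.

    ``per_line_counts`` is a sequence of counts, one per line (zeros
    included); when omitted the SE is computed as if events were spread as
    evenly as the total allows, which is only appropriate for display.
    """
    sg = design.site_generations
    if sg <= 0:
        raise ValueError("site-generations denominator is zero")
    if per_line_counts is None:
        per_line_counts = [count / design.n_lines] * design.n_lines
    per_line_counts = np.asarray(per_line_counts, dtype=float)
    if len(per_line_counts) != design.n_lines:
        raise ValueError("per_line_counts length must equal n_lines")
    if int(round(per_line_counts.sum())) != count and per_line_counts.sum() != count:
        raise ValueError("per-line counts do not sum to the total count")
    per_line_rates = per_line_counts / (
        design.generations * design.analyzed_length_bp
    )
    se = (
        per_line_rates.std(ddof=1) / math.sqrt(design.n_lines)
        if design.n_lines > 1
        else 0.0
    )
    return RateEstimate(
        event_class=event_class,
        count=count,
        rate=count / sg,
        se=float(se),
        site_generations=sg,
        per_line_rates=per_line_rates,
    )


@dataclass
class SpectrumTable:
    """Counts and conditional per-site rates for the six SNM classes."""

    counts: dict[str, int]
    at_sites: float
    gc_sites: float
    total_generations: float
    conditional_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.conditional_rates:
            self.conditional_rates = {
                c: self.counts[c] / (self._source_sites(c) * self.total_generations)
                if self._source_sites(c) > 0
                else float("nan")
                for c in SNM_CLASSES
            }

    def _source_sites(self, cls: str) -> float:
        return self.gc_sites if cls.startswith("GC") else self.at_sites

    @property
    def total_count(self) -> int:
        return int(sum(self.counts.values()))

    # --- directional fold biases -------------------------------------------------
    @property
    def gc_to_at_fold(self) -> float:
        """Overall G/C->A/T vs A/T->G/C conditional-rate fold."""
        u = self.conditional_rates["AT>GC_ts"] + self.conditional_rates["AT>CG_tv"]
        v = self.conditional_rates["GC>AT_ts"] + self.conditional_rates["GC>TA_tv"]
        return v / u

    @property
    def transition_fold(self) -> float:
        """G:C->A:T vs A:T->G:C within transitions."""
        return (
            self.conditional_rates["GC>AT_ts"] / self.conditional_rates["AT>GC_ts"]
        )

    @property
    def transversion_fold(self) -> float:
        """G:C->T:A vs A:T->C:G within transversions."""
        return (
            self.conditional_rates["GC>TA_tv"] / self.conditional_rates["AT>CG_tv"]
        )


def spectrum_counts_from_events(events, include_clustered: bool = False) -> dict:
    """Tally the six-class counts from classified events.

    By default only lone SNM events count; ``include_clustered`` adds the SNM
    members of double and complex events.
    """
    counts = {c: 0 for c in SNM_CLASSES}
    for e in events:
        if e.event_class == "SNM" or (
            include_clustered and e.event_class in ("double_SNM", "complex")
        ):
            for ref, alt in e.snm_changes:
                counts[snm_class_of(ref, alt)] += 1
    return counts


def conditional_spectrum(
    snm_events,
    composition,
    design: ExperimentDesign,
    include_clustered: bool = False,
) -> SpectrumTable:
    counts = spectrum_counts_from_events(snm_events, include_clustered)
    return SpectrumTable(
        counts=counts,
        at_sites=composition.at_sites,
        gc_sites=composition.gc_sites,
        total_generations=design.total_generations,
    )


def spectrum_from_counts(counts: dict, gc_fraction: float,
                         total_generations: float = 1.0,
                         total_sites: float = 1.0) -> SpectrumTable:
    """Build a spectrum directly from class counts and a G/C fraction."""
    return SpectrumTable(
        counts=dict(counts),
        at_sites=total_sites * (1.0 - gc_fraction),
        gc_sites=total_sites * gc_fraction,
        total_generations=total_generations,
    )


def ts_tv(spectrum: SpectrumTable) -> float:
    """Transition / transversion count ratio."""
    tv = sum(spectrum.counts[c] for c in TRANSVERSIONS)
    if tv == 0:
        raise ValueError("no transversions observed; Ts/Tv undefined")
    return sum(spectrum.counts[c] for c in TRANSITIONS) / tv


def equilibrium_gc(spectrum: SpectrumTable) -> float:
    """Mutational-equilibrium G/C fraction u/(u+v).

    u is the conditional A/T->G/C rate (AT>GC plus AT>CG); v is the
    conditional G/C->A/T rate (GC>AT plus GC>TA).  G/C<->C/G and A/T<->T/A
    changes leave composition unchanged and do not enter.
    """
    u = spectrum.conditional_rates["AT>GC_ts"] + spectrum.conditional_rates["AT>CG_tv"]
    v = spectrum.conditional_rates["GC>AT_ts"] + spectrum.conditional_rates["GC>TA_tv"]
    if u == 0 and v == 0:
        raise ValueError("both directional rates are zero; equilibrium undefined")
    return u / (u + v)


def effective_population_size(pi: float, mu: float) -> float:
    """Haploid coalescent expectation pi = 2 Ne mu, solved for Ne."""
    if pi <= 0 or mu <= 0:
        raise ValueError("pi and mu must be positive")
    return pi / (2.0 * mu)


def divergence_generations(n_diffs: float, mu: float, L: float) -> float:
    """Generations separating two strains given n neutral differences."""
    if mu <= 0 or L <= 0:
        raise ValueError("mu and L must be positive")
    return n_diffs / (mu * L)


# ----------------------------------------------------------------------------
# per-line count distribution fits
# ----------------------------------------------------------------------------


@dataclass
class DistributionFit:
    model: str
    mean: float
    loglik: float
    n_params: int
    aic: float
    k: float | None = None  # NB overdispersion: var = mean + mean^2/k
    gof_chi2: float | None = None
    gof_df: int | None = None
    gof_p: float | None = None


def _gof_chisquare(counts, pmf, n_params, min_expected: float = 1.0):
    """Chi-square goodness of fit with bins pooled so each expected >= 1."""
    counts = np.asarray(counts)
    n = len(counts)
    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 1).astype(float)
    probs = np.array([pmf(i) for i in range(kmax + 1)])
    probs = np.append(probs, max(1.0 - probs.sum(), 0.0))  # right tail
    observed = np.append(observed, 0.0)
    expected = probs * n
    # pool adjacent cells (from the right) until every expected >= min_expected
    obs_b, exp_b = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed[::-1], expected[::-1]):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_b.append(acc_o)
            exp_b.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if exp_b:
            obs_b[-1] += acc_o
            exp_b[-1] += acc_e
        else:
            obs_b, exp_b = [acc_o], [acc_e]
    obs_b, exp_b = np.array(obs_b[::-1]), np.array(exp_b[::-1])
    df = len(obs_b) - 1 - n_params
    chi2 = float(((obs_b - exp_b) ** 2 / exp_b).sum())
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return chi2, df, p


def _fit_poisson(counts) -> DistributionFit:
    counts = np.asarray(counts)
    m = float(counts.mean())
    loglik = float(stats.poisson.logpmf(counts, m).sum())
    fit = DistributionFit(model="Poisson", mean=m, loglik=loglik, n_params=1,
                          aic=2 * 1 - 2 * loglik)
    fit.gof_chi2, fit.gof_df, fit.gof_p = _gof_chisquare(
        counts, lambda i: stats.poisson.pmf(i, m), n_params=1
    )
    return fit


def _fit_negative_binomial(counts) -> DistributionFit:
    counts = np.asarray(counts)
    m = float(counts.mean())  # MLE of the mean for any fixed k

    def negll(log_k):
        k = math.exp(log_k)
        return -float(stats.nbinom.logpmf(counts, k, k / (k + m)).sum())

    res = optimize.minimize_scalar(negll, bounds=(-6, 12), method="bounded")
    k = math.exp(res.x)
    loglik = -res.fun
    fit = DistributionFit(model="NegativeBinomial", mean=m, k=k, loglik=loglik,
                          n_params=2, aic=2 * 2 - 2 * loglik)
    fit.gof_chi2, fit.gof_df, fit.gof_p = _gof_chisquare(
        counts, lambda i: stats.nbinom.pmf(i, k, k / (k + m)), n_params=2
    )
    return fit


def relative_likelihood(aic: float, aic_min: float) -> float:
    """exp((AIC_min - AIC)/2): how likely a model is relative to the best."""
    return math.exp((aic_min - aic) / 2.0)


def fit_count_distribution(per_line_counts):
    """ML Poisson and negative-binomial fits to per-line mutation counts.

    Returns (poisson_fit, nb_fit_or_None, comparison dict).  With all counts
    identical the NB likelihood is maximized at k -> infinity (no
    overdispersion); the NB fit is skipped and noted.
    """
    counts = np.asarray(per_line_counts, dtype=int)
    if len(counts) < 5:
        raise ValueError("need at least 5 lines to fit count distributions")
    pois = _fit_poisson(counts)
    if counts.min() == counts.max():
        return pois, None, {
            "note": "all counts identical; negative binomial degenerate",
            "best": "Poisson",
        }
    nb = _fit_negative_binomial(counts)
    aic_min = min(pois.aic, nb.aic)
    comparison = {
        "best": "Poisson" if pois.aic <= nb.aic else "NegativeBinomial",
        "delta_aic": pois.aic - nb.aic,
        "relative_likelihood_poisson": relative_likelihood(pois.aic, aic_min),
        "relative_likelihood_nb": relative_likelihood(nb.aic, aic_min),
    }
    return pois, nb, comparison
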