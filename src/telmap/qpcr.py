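"""qPCR copy-number phenotyping.

Telomere length in *Drosophila* is proxied by the genomic copy number
of the telomeric retrotransposon *HeT-A*, measured by quantitative PCR
of its GAG ORF against a single-copy reference gene (RpS17). This
module turns replicate Ct values into relative copy numbers via the
standard 2^-ddCt method, calls telomere elongation from multi-generation
dCt trajectories, screens a panel's copy-number distribution for
log-normal outliers, and sizes PCR amplicons in silico.

Conventions
-----------
dCt      = mean target Ct - mean reference-gene Ct (lower = more copies)
ddCt     = dCt(sample) - dCt(calibrator)
relative copy number = 2^-ddCt  (calibrator-normalized)

The panel outlier screen operates on log10 copy numbers because panel
copy numbers are well described by a log-normal distribution; a line is
flagged when its log10 value exceeds the fitted log-mean by more than
``k`` log-SDs (one-pass screen, fit on all values, k = 3 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .variants import RegionSequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate cycle-threshold values for one sample x gene (x generation)."""

    sample_id: str
    gene: str
    replicates: tuple[float, ...]
    generation: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(float(c) for c in self.replicates))
        if not self.replicates:
            raise ValueError(f"no Ct replicates for {self.sample_id}/{self.gene}")
        for c in self.replicates:
            if not (0.0 < c <= 45.0):
                raise ValueError(
                    f"Ct {c} outside (0, 45] for {self.sample_id}/{self.gene}"
                )

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        """Sample SD of replicates (0 for a single replicate)."""
        if len(self.replicates) < 2:
            return 0.0
        return float(np.std(self.replicates, ddof=1))


@dataclass(frozen=True)
class DeltaCt:
    """Target-minus-reference Ct for one sample, with propagated replicate SD."""

    sample_id: str
    value: float
    sd: float
    generation: int | None = None


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    delta_ct: float
    relative_copy_number: float
    replicate_sd: float


@dataclass(frozen=True)
class ElongationCall:
    """Per-recombinant verdict: did telomeres elongate over the assayed
    generations?"""

    recombinant_id: str
    elongated: bool
    fold_change: float
    slope: float  # dCt per generation; negative means copy gain


@dataclass(frozen=True)
class PanelScreenResult:
    values: Mapping[str, float]
    log_mean: float
    log_sd: float
    k: float
    tail: str
    flagged: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product on the forward strand of the template.

    ``start``/``end`` are 1-based inclusive template coordinates of the
    outermost primer bases; ``length = end - start + 1``.
    """

    start: int
    end: int
    length: int


def delta_ct(target: CtMeasurement, reference: CtMeasurement) -> DeltaCt:
    """dCt = mean(target Ct) - mean(reference-gene Ct).

    Replicate SDs of the two means are propagated in quadrature. The
    two measurements must come from the same sample.
    """
    if target.sample_id != reference.sample_id:
        raise ValueError(
            f"sample mismatch: {target.sample_id!r} vs {reference.sample_id!r}"
        )
    sd = math.hypot(target.sd, reference.sd)
    return DeltaCt(
        sample_id=target.sample_id,
        value=target.mean - reference.mean,
        sd=sd,
        generation=target.generation,
    )


def relative_copy_number(sample_dct: float, calibrator_dct: float) -> float:
    """2^-(dCt_sample - dCt_calibrator): copy number relative to the
    calibrator strain (one qPCR cycle = one two-fold change)."""
    if not (math.isfinite(sample_dct) and math.isfinite(calibrator_dct)):
        raise ValueError("dCt values must be finite")
    return 2.0 ** (-(sample_dct - calibrator_dct))


def call_elongation(
    recombinant_id: str,
    trajectory: Sequence[tuple[int, float]],
    fold_threshold: float = 2.0,
    use_regression: bool = False,
) -> ElongationCall:
    """Call telomere elongation from a (generation, dCt) trajectory.

    Fold change is 2^(dCt_gen0 - dCt_genLast): a drop in dCt over the
    assayed generations means the target gained copies relative to the
    single-copy gene. ``elongated`` requires fold change >=
    ``fold_threshold`` and, when ``use_regression`` is set, additionally
    a negative least-squares slope of dCt on generation.
    """
    if len(trajectory) < 2:
        raise ValueError("need dCt at two or more generations")
    pts = sorted((int(g), float(d)) for g, d in trajectory)
    gens = [g for g, _ in pts]
    if gens[0] != 0:
        raise ValueError("trajectory must include generation 0")
    if len(set(gens)) != len(gens):
        raise ValueError("duplicate generations in trajectory")
    dct0 = pts[0][1]
    dct_last = pts[-1][1]
    fold = 2.0 ** (dct0 - dct_last)
    slope = float(np.polyfit(gens, [d for _, d in pts], 1)[0])
    elongated = fold >= fold_threshold
    if use_regression:
        elongated = elongated and slope < 0.0
    return ElongationCall(recombinant_id, elongated, fold, slope)


def fit_panel_distribution(values: Sequence[float]) -> tuple[float, float]:
    """Moment fit of a log-normal: mean and sample SD of log10 values."""
    if len(values) < 3:
        raise ValueError("need at least 3 copy-number values to fit")
    for i, v in enumerate(values):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"non-positive copy number at index {i}: {v}")
    logs = np.log10(np.asarray(values, dtype=float))
    return float(np.mean(logs)), float(np.std(logs, ddof=1))


def flag_outliers(
    values: Mapping[str, float],
    k: float = 3.0,
    tail: str = "high",
    refit: bool = False,
) -> PanelScreenResult:
    """Screen panel copy numbers for outliers on the log10 scale.

    Lines with log10(value) > log_mean + k * log_sd are flagged (and
    symmetrically below when ``tail="both"``). The fit includes all
    values (one-pass screen); ``refit=True`` re-fits after removing
    flags and repeats until stable, for heavily contaminated panels.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if tail not in ("high", "both"):
        raise ValueError(f"tail must be 'high' or 'both', got {tail!r}")
    ids = list(values)
    for line, v in values.items():
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"non-positive copy number for line {line!r}: {v}")
    kept = set(ids)
    while True:
        mu, sd = fit_panel_distribution([values[i] for i in kept] if refit else
                                        [values[i] for i in ids])
        flagged = []
        for line in ids:
            z_hi = math.log10(values[line]) > mu + k * sd
            z_lo = tail == "both" and math.log10(values[line]) < mu - k * sd
            if z_hi or z_lo:
                flagged.append(line)
        if not refit or set(ids) - set(flagged) == kept:
            return PanelScreenResult(
                values=dict(values), log_mean=mu, log_sd=sd, k=k, tail=tail,
                flagged=tuple(flagged),
            )
        kept = set(ids) - set(flagged)
        if len(kept) < 3:
            raise ValueError("refit removed too many lines to keep fitting")


def in_silico_pcr(
    template: str | RegionSequence,
    forward: str,
    reverse: str,
    max_length: int = 5000,
) -> list[Amplicon]:
    """Predict PCR products by exact primer matching.

    The forward primer is matched on the given strand; the reverse
    primer binds the opposite strand, so its reverse complement is
    matched downstream on the template. Every forward/reverse pairing
    producing a product of at most ``max_length`` bp is reported.
    Primers shorter than 10 bases are rejected as unrealistically
    promiscuous.
    """
    seq = template.seq if isinstance(template, RegionSequence) else template
    seq = seq.upper()
    forward = forward.upper()
    reverse = reverse.upper()
    if len(forward) < 10 or len(reverse) < 10:
        raise ValueError("primers must be at least 10 bases")

    def _all_hits(text: str, pat: str) -> list[int]:
        hits, i = [], text.find(pat)
        while i != -1:
            hits.append(i)
            i = text.find(pat, i + 1)
        return hits

    rc = _revcomp(reverse)
    products = []
    for f0 in _all_hits(seq, forward):
        for r0 in _all_hits(seq, rc):
            if r0 < f0:
                continue  # reverse site upstream of forward site: no product
            end = r0 + len(rc)  # 0-based exclusive end of reverse site
            length = end - f0
            if length < max(len(forward), len(reverse)):
                continue  # sites overlap so far that one primer is not contained
            if length <= max_length:
                products.append(Amplicon(start=f0 + 1, end=end, length=length))
    return sorted(products, key=lambda a: (a.start, a.end))
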