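"""Expansion profiles, the ratio-of-CAG-expansions statistic, allele
eligibility against stutter interference, and tissue contrasts.

The instability statistic is the ratio of reads carrying 1-10 more CAG than
the inherited allele to reads at the inherited length,

    ratio = sum_{i=1..10} n_{+i} / n .

Amplification of a single template molecule already produces a nonzero ratio
from forward PCR slippage alone; a measured ratio is evidence of genuine
somatic expansion only when it exceeds that single-molecule baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from scipy.stats import binomtest

from .errors import BaselineMismatchError, UndefinedFoldError, UndefinedRatioError
from .repeat_genotyper import AlleleStructure, SampleGenotype, VariantTag

DEFAULT_WINDOW = 10
DEFAULT_GUARD = 2


@dataclass(frozen=True)
class ExpansionProfile:
    """Per-allele read-length histogram summary and expansion ratio.

    ``n`` counts reads at the inherited length for the allele's variant
    structure; ``n_plus[i-1]`` counts reads at inherited + i CAG with the
    same structure, i = 1..window.  Reads further than +window are excluded
    from the ratio but kept in ``raw_histogram``.
    """

    inherited_cag: int
    n: int
    n_plus: tuple[int, ...]
    sample_id: str = ""
    allele_role: str = "long"          # "short" | "long"
    tissue: str = ""
    variant_tag: VariantTag = "canonical"
    raw_histogram: dict[tuple[VariantTag, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise UndefinedRatioError(
                f"no reads at inherited length {self.inherited_cag}; ratio undefined")
        if any(c < 0 for c in self.n_plus):
            raise ValueError("n_plus counts must be >= 0")

    @property
    def window(self) -> int:
        return len(self.n_plus)

    @property
    def ratio(self) -> float:
        return sum(self.n_plus) / self.n


@dataclass(frozen=True)
class BaselineModel:
    """Expected expansion ratio from PCR slippage alone, per inherited length."""

    inherited_cag: int
    baseline_ratio: float
    source: str = "single_molecule_experiment"  # or "simulator"

    def __post_init__(self) -> None:
        if self.baseline_ratio < 0:
            raise ValueError("baseline_ratio must be >= 0")

    @classmethod
    def from_json(cls, path) -> "BaselineModel":
        data = json.loads(Path(path).read_text())
        return cls(inherited_cag=data["inherited_cag"],
                   baseline_ratio=data["baseline_ratio"],
                   source=data.get("source", "single_molecule_experiment"))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "inherited_cag": self.inherited_cag,
            "baseline_ratio": self.baseline_ratio,
            "source": self.source,
        }, indent=2) + "\n")


def compute_expansion_ratio(
    histogram: dict[tuple[VariantTag, int], int],
    allele: AlleleStructure,
    window: int = DEFAULT_WINDOW,
    sample_id: str = "",
    allele_role: str = "long",
    tissue: str = "",
) -> ExpansionProfile:
    """Build the expansion profile of one inherited allele.

    Expanded reads are counted only when their variant structure matches the
    inherited allele's, which keeps products of the other allele (or of a
    structurally distinct variant) out of the numerator.
    """
    n = histogram.get((allele.variant_tag, allele.cag), 0)
    if n <= 0:
        raise UndefinedRatioError(
            f"no reads at inherited length {allele.cag} "
            f"({allele.variant_tag}); ratio undefined")
    n_plus = tuple(
        histogram.get((allele.variant_tag, allele.cag + i), 0)
        for i in range(1, window + 1)
    )
    return ExpansionProfile(
        inherited_cag=allele.cag, n=n, n_plus=n_plus,
        sample_id=sample_id, allele_role=allele_role, tissue=tissue,
        variant_tag=allele.variant_tag, raw_histogram=dict(histogram),
    )


def allele_eligibility(
    genotype: SampleGenotype,
    window: int = DEFAULT_WINDOW,
    guard: int = DEFAULT_GUARD,
) -> dict[str, tuple[bool, str]]:
    """Decide which alleles can be scored without stutter interference.

    Backward slippage products of the longer allele fall up to a few CAG
    below it; if the shorter allele's expansion window (+1..+window, plus a
    guard band) reaches into that zone and the two alleles share the same
    variant structure, the shorter allele cannot be scored reliably.

    The longer allele is always eligible.  The shorter allele is eligible iff
    (a) its variant structure differs from the longer allele's, or
    (b) the CAG gap exceeds window + guard.
    """
    short, long_ = genotype.allele_short, genotype.allele_long
    out = {"long": (True, "longer allele is always eligible")}
    if genotype.is_homozygous:
        out["short"] = (True, "homozygous call: single scored allele")
        return out
    gap = long_.cag - short.cag
    if short.variant_tag != long_.variant_tag:
        out["short"] = (True,
                        "structures distinguishable "
                        f"({short.variant_tag} vs {long_.variant_tag})")
    elif gap > window + guard:
        out["short"] = (True, f"CAG gap {gap} > window+guard {window + guard}")
    else:
        out["short"] = (False,
                        f"CAG gap {gap} <= window+guard {window + guard} with "
                        "identical structure: longer-allele backward stutter "
                        "interferes")
    return out


def is_genuine_expansion(
    profile: ExpansionProfile,
    baseline: BaselineModel,
    binomial_test: bool = False,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Strict point comparison of a measured ratio against the stutter baseline.

    Returns (genuine, margin) with margin = ratio - baseline_ratio.  With
    ``binomial_test=True`` the call additionally requires a one-sided
    binomial test of the expanded-read count against the baseline expectation
    to reject at ``alpha`` (off by default: the headline argument is the
    point comparison).
    """
    if profile.inherited_cag != baseline.inherited_cag:
        raise BaselineMismatchError(
            f"profile inherited_cag {profile.inherited_cag} != "
            f"baseline {baseline.inherited_cag}")
    margin = profile.ratio - baseline.baseline_ratio
    genuine = profile.ratio > baseline.baseline_ratio
    if genuine and binomial_test:
        k = sum(profile.n_plus)
        total = profile.n + k
        p0 = baseline.baseline_ratio / (1.0 + baseline.baseline_ratio)
        test = binomtest(k, total, p0, alternative="greater")
        genuine = test.pvalue < alpha
    return genuine, margin


def tissue_fold_change(
    profile_a: ExpansionProfile,
    profile_b: ExpansionProfile,
    i: int,
) -> float:
    """Fold change of the +i expansion frequency between two tissues,
    (n_plus_a[i]/n_a) / (n_plus_b[i]/n_b)."""
    if profile_a.inherited_cag != profile_b.inherited_cag:
        raise BaselineMismatchError(
            "profiles refer to different inherited alleles: "
            f"{profile_a.inherited_cag} vs {profile_b.inherited_cag}")
    if not 1 <= i <= min(profile_a.window, profile_b.window):
        raise ValueError(f"offset {i} outside both profiles' windows")
    fb = profile_b.n_plus[i - 1] / profile_b.n
    if fb == 0:
        raise UndefinedFoldError(f"zero +{i} frequency in denominator profile")
    fa = profile_a.n_plus[i - 1] / profile_a.n
    return fa / fb
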