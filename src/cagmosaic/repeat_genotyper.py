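"""Per-read repeat decomposition and inherited-allele genotyping.

Amplicon reads covering an HTT-exon-1-like locus are reduced to a repeat
structure ``(CAG)n (CAACAG)m (CCGCCA)k (CCG)p (CCT)q`` by locating the two
constant flanking anchors and greedily decomposing the inter-anchor segment
left-to-right, unit by unit, with no backtracking.  A read passes only when
the decomposition consumes the whole segment.  The two inherited alleles of a
sample are then called from the (variant_tag, cag) read-length histogram by
stutter-aware peak calling: local maxima are candidate alleles, and a peak
sitting within a small window *below* a larger same-structure peak is absorbed
as backward PCR stutter.

The ``cag`` field counts only the pure uninterrupted CAG tract; the CAA-CAG
half of the interruption cassette is not included.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import yaml

from .errors import AmbiguousGenotypeError, InsufficientReadsError

VariantTag = Literal["canonical", "loss_of_interruption", "other"]
ReadStatus = Literal["pass", "no_anchor", "ambiguous_decomposition", "low_quality"]

#: Decomposition units, in locus order.
UNITS = ("CAG", "CAACAG", "CCGCCA", "CCG", "CCT")


@dataclass(frozen=True)
class AlleleStructure:
    """A repeat allele: pure-CAG length plus interruption-cassette composition.

    ``variant_tag`` is derived, never set: ``loss_of_interruption`` exactly
    when the whole CAACAG-CCGCCA intervening sequence is absent,
    ``canonical`` for the single-cassette reference structure, ``other``
    for any remaining composition (e.g. a duplicated CAACAG cassette).
    """

    cag: int
    caacag: int = 1
    ccgcca: int = 1
    ccg: int = 7
    cct: int = 2
    variant_tag: VariantTag = field(init=False)

    def __post_init__(self) -> None:
        if self.cag < 1:
            raise ValueError("cag must be >= 1")
        if min(self.caacag, self.ccgcca, self.ccg, self.cct) < 0:
            raise ValueError("cassette counts must be >= 0")
        if self.caacag == 0 and self.ccgcca == 0:
            tag = "loss_of_interruption"
        elif self.caacag == 1 and self.ccgcca == 1:
            tag = "canonical"
        else:
            tag = "other"
        object.__setattr__(self, "variant_tag", tag)

    def to_sequence(self) -> str:
        """Render the repeat region (anchors excluded) as a DNA string."""
        return (
            "CAG" * self.cag
            + "CAACAG" * self.caacag
            + "CCGCCA" * self.ccgcca
            + "CCG" * self.ccg
            + "CCT" * self.cct
        )

    def with_cag(self, cag: int) -> "AlleleStructure":
        """Same cassette composition with a different pure-CAG length."""
        return AlleleStructure(cag=cag, caacag=self.caacag, ccgcca=self.ccgcca,
                               ccg=self.ccg, cct=self.cct)


@dataclass(frozen=True)
class ReadCall:
    """One read reduced to its repeat structure (present iff status == pass)."""

    read_id: str
    status: ReadStatus
    structure: AlleleStructure | None = None

    def __post_init__(self) -> None:
        if (self.structure is not None) != (self.status == "pass"):
            raise ValueError("structure must be present exactly when status == 'pass'")


@dataclass(frozen=True)
class SampleGenotype:
    """Called inherited alleles plus the full pass-read histogram."""

    allele_short: AlleleStructure
    allele_long: AlleleStructure
    histogram_by_structure: dict[tuple[VariantTag, int], int]
    total_pass_reads: int

    def __post_init__(self) -> None:
        if self.allele_short.cag > self.allele_long.cag:
            raise ValueError("allele_short.cag must be <= allele_long.cag")
        if sum(self.histogram_by_structure.values()) != self.total_pass_reads:
            raise ValueError("histogram counts must sum to total_pass_reads")

    @property
    def is_homozygous(self) -> bool:
        return self.allele_short == self.allele_long


# HTT-exon-1-like constant flanks used by the default locus configuration:
# 24 nt immediately 5' of the CAG tract and 21 nt immediately 3' of the
# (CCT) tract.
DEFAULT_ANCHOR_5P = "GCCTTCGAGTCCCTCAAGTCCTTC"
DEFAULT_ANCHOR_3P = "CAGCTTCCTCAGCCGCCGCCG"


@dataclass
class LocusConfig:
    """Locus and genotyping thresholds (YAML-serialisable)."""

    anchor_5p: str = DEFAULT_ANCHOR_5P
    anchor_3p: str = DEFAULT_ANCHOR_3P
    max_mismatch: int = 2
    min_reads: int = 100
    homozygosity_fraction: float = 0.85
    stutter_absorb_window: int = 2
    min_peak_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "LocusConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "anchor_5p": self.anchor_5p,
            "anchor_3p": self.anchor_3p,
            "max_mismatch": self.max_mismatch,
            "min_reads": self.min_reads,
            "homozygosity_fraction": self.homozygosity_fraction,
            "stutter_absorb_window": self.stutter_absorb_window,
            "min_peak_fraction": self.min_peak_fraction,
        }


def _find_approx(seq: str, pattern: str, start: int, max_mismatch: int) -> int:
    """Leftmost start index of `pattern` in `seq[start:]` with at most
    `max_mismatch` substitutions (no indels), or -1."""
    exact = seq.find(pattern, start)
    if exact != -1 or max_mismatch == 0:
        return exact
    m = len(pattern)
    n = len(seq) - start
    if n < m:
        return -1
    arr = np.frombuffer(seq[start:].encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mism = (windows != pat).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return -1 if hits.size == 0 else start + int(hits[0])


def greedy_decompose(segment: str) -> AlleleStructure | None:
    """Greedy left-to-right unit decomposition of the inter-anchor segment.

    Consumes as many CAG units as possible, then CAACAG, CCGCCA, CCG and CCT
    in that fixed order, without backtracking.  Returns None unless the whole
    segment is consumed and at least one CAG unit was found.
    """
    counts = []
    pos = 0
    for unit in UNITS:
        k = len(unit)
        c = 0
        while segment.startswith(unit, pos):
            pos += k
            c += 1
        counts.append(c)
    if pos != len(segment) or counts[0] < 1:
        return None
    return AlleleStructure(cag=counts[0], caacag=counts[1], ccgcca=counts[2],
                           ccg=counts[3], cct=counts[4])


def anchor_and_decompose(
    read_sequence: str,
    anchors: tuple[str, str] = (DEFAULT_ANCHOR_5P, DEFAULT_ANCHOR_3P),
    max_mismatch: int = 2,
    read_id: str = "",
) -> ReadCall:
    """Locate both flanking anchors and decompose the segment between them.

    Anchors must match with at most ``max_mismatch`` substitutions each
    (indels in anchors are not tolerated).  Status is ``no_anchor`` when
    either flank is absent, ``ambiguous_decomposition`` when residual bases
    remain after greedy decomposition, ``pass`` otherwise.
    """
    if not read_sequence:
        raise ValueError("read_sequence must be non-empty")
    a5, a3 = anchors
    if len(read_sequence) < len(a5) + len(a3) + 3:
        return ReadCall(read_id=read_id, status="low_quality")
    i5 = _find_approx(read_sequence, a5, 0, max_mismatch)
    if i5 == -1:
        return ReadCall(read_id=read_id, status="no_anchor")
    seg_start = i5 + len(a5)
    i3 = _find_approx(read_sequence, a3, seg_start, max_mismatch)
    if i3 == -1:
        return ReadCall(read_id=read_id, status="no_anchor")
    structure = greedy_decompose(read_sequence[seg_start:i3])
    if structure is None:
        return ReadCall(read_id=read_id, status="ambiguous_decomposition")
    return ReadCall(read_id=read_id, status="pass", structure=structure)


def decompose_reads(
    reads: Iterable[tuple[str, str]],
    locus: LocusConfig | None = None,
) -> Iterator[ReadCall]:
    """Decompose (read_id, sequence) pairs, memoising identical sequences.

    Amplicon read sets are dominated by a few exact repeat-length classes, so
    a per-call sequence cache removes almost all redundant parsing.
    """
    locus = locus or LocusConfig()
    anchors = (locus.anchor_5p, locus.anchor_3p)
    cache: dict[str, ReadCall] = {}
    for read_id, seq in reads:
        hit = cache.get(seq)
        if hit is None:
            hit = anchor_and_decompose(seq, anchors, locus.max_mismatch, read_id="")
            cache[seq] = hit
        yield ReadCall(read_id=read_id, status=hit.status, structure=hit.structure)


def histogram_from_calls(
    read_calls: Iterable[ReadCall],
) -> dict[tuple[VariantTag, int], int]:
    """(variant_tag, cag) -> pass-read count."""
    counts: Counter = Counter()
    for call in read_calls:
        if call.status == "pass":
            assert call.structure is not None
            counts[(call.structure.variant_tag, call.structure.cag)] += 1
    return dict(counts)


def _call_peaks(
    histogram: dict[tuple[VariantTag, int], int],
    stutter_window: int,
    min_peak_fraction: float,
) -> list[tuple[tuple[VariantTag, int], int]]:
    """Stutter-aware peak calling on the per-structure length histogram.

    Candidate peaks are local maxima of each variant_tag's length profile,
    above a noise floor of ``min_peak_fraction`` of the global maximum count.
    A candidate with a strictly larger same-tag bin within ``stutter_window``
    CAG on either side is absorbed: below a larger peak it is backward
    stutter, above one it is a forward-slippage / somatic-expansion shoulder.
    Alleles closer than the window are inherently unresolvable here.
    """
    max_count = max(histogram.values())
    floor = min_peak_fraction * max_count
    surviving: list[tuple[tuple[VariantTag, int], int]] = []
    tags = {tag for tag, _ in histogram}
    for tag in tags:
        prof = {cag: c for (t, cag), c in histogram.items() if t == tag}
        for cag, c in prof.items():
            left, right = prof.get(cag - 1, 0), prof.get(cag + 1, 0)
            if not (c > left and c >= right and c >= floor):
                continue
            absorbed = any(
                prof.get(cag + d, 0) > c
                for d in range(-stutter_window, stutter_window + 1)
                if d != 0
            )
            if not absorbed:
                surviving.append(((tag, cag), c))
    surviving.sort(key=lambda item: (-item[1], item[0][1]))
    return surviving


def _representative_structure(
    read_calls: Sequence[ReadCall], tag: VariantTag, cag: int
) -> AlleleStructure:
    """Modal full structure among pass reads at a (tag, cag) peak."""
    counter: Counter = Counter()
    for call in read_calls:
        s = call.structure
        if s is not None and s.variant_tag == tag and s.cag == cag:
            counter[s] += 1
    return counter.most_common(1)[0][0]


def genotype_sample(
    read_calls: Iterable[ReadCall],
    min_reads: int = 100,
    homozygosity_fraction: float = 0.85,
    stutter_window: int = 2,
    min_peak_fraction: float = 0.05,
) -> SampleGenotype:
    """Call the sample's two inherited alleles from its read-length histogram.

    The two modal (variant_tag, cag) peaks after stutter-aware peak calling
    become the inherited alleles; a homozygous call is made when the top peak
    holds more than ``homozygosity_fraction`` of the surviving-peak reads.

    Raises
    ------
    InsufficientReadsError
        fewer than ``min_reads`` passing calls.
    AmbiguousGenotypeError
        more than two peaks survive.
    """
    calls = [c for c in read_calls]
    passing = [c for c in calls if c.status == "pass"]
    if len(passing) < min_reads:
        raise InsufficientReadsError(
            f"{len(passing)} passing reads < min_reads={min_reads}")
    histogram = histogram_from_calls(passing)
    peaks = _call_peaks(histogram, stutter_window, min_peak_fraction)
    if len(peaks) > 2:
        raise AmbiguousGenotypeError(
            f"{len(peaks)} surviving peaks: {[(k, c) for k, c in peaks]}")
    peak_total = sum(c for _, c in peaks)
    (top_key, top_count) = peaks[0]
    if len(peaks) == 1 or top_count / peak_total > homozygosity_fraction:
        allele = _representative_structure(passing, *top_key)
        short_allele = long_allele = allele
    else:
        a = _representative_structure(passing, *peaks[0][0])
        b = _representative_structure(passing, *peaks[1][0])
        short_allele, long_allele = sorted((a, b), key=lambda s: s.cag)
    return SampleGenotype(
        allele_short=short_allele,
        allele_long=long_allele,
        histogram_by_structure=histogram,
        total_pass_reads=len(passing),
    )
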