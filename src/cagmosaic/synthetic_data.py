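"""Synthetic read sets and cohorts with the statistical structure the
somatic-expansion analysis assumes.

PCR stutter model
-----------------
Amplification is a per-cycle branching process: every molecule produces one
copy per cycle, and each copy event independently loses one repeat unit with
probability ``p_minus`` or gains one with probability ``p_plus`` (single-unit
slips only; backward slips dominate).  Slip probabilities scale as
``length_scaling ** (cag - reference_cag)``, so longer tracts stutter more.
Because expectation is linear even though the process is multiplicative, the
expected final product-length distribution can be computed exactly with a
small transition recurrence; that expectation model is used both to calibrate
``p_plus`` against the single-molecule benchmark (only +1 products, at 2.3 %
of the inherited-length products for a 33 CAG template) and to invert
measured-ratio targets into template-pool expansion frequencies.

Somatic mosaicism is modelled at the template-pool stage: a fraction of input
molecules carries ``inherited + i`` CAG before amplification begins.

Reads are rendered as ``5'anchor + repeat structure + 3'anchor`` with a
uniform per-base substitution error.
"""

from __future__ import annotations

import gzip
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .repeat_genotyper import (
    DEFAULT_ANCHOR_3P,
    DEFAULT_ANCHOR_5P,
    AlleleStructure,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _load_config_yaml(name: str) -> dict:
    ref = importlib.resources.files("cagmosaic") / "config" / name
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class StutterParams:
    """Per-cycle PCR slippage model.

    p_minus / p_plus : per-copy-event probability of losing / gaining one
        repeat unit at ``reference_cag``; backward bias requires
        ``p_minus >= p_plus`` by default.
    cycles : number of PCR cycles.
    length_scaling : multiplicative change in slip probability per additional
        CAG relative to ``reference_cag``.
    """

    p_minus: float = 0.01
    p_plus: float = 0.00153
    cycles: int = 30
    length_scaling: float = 1.05
    reference_cag: int = 33

    def __post_init__(self) -> None:
        if self.p_minus < 0 or self.p_plus < 0:
            raise ValueError("slip probabilities must be >= 0")
        if self.p_minus + self.p_plus >= 1:
            raise ValueError("p_minus + p_plus must be < 1 per cycle")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.length_scaling <= 0:
            raise ValueError("length_scaling must be > 0")

    def slip_probs(self, cag: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """(p_minus, p_plus) at absolute tract length(s), capped so their sum < 1."""
        scale = np.asarray(self.length_scaling, dtype=float) ** (np.asarray(cag) - self.reference_cag)
        pm = np.minimum(self.p_minus * scale, 0.45)
        pp = np.minimum(self.p_plus * scale, 0.45)
        return pm, pp

    @classmethod
    def calibrated_default(cls) -> "StutterParams":
        """Defaults from the versioned calibration config file."""
        cfg = _load_config_yaml("stutter_defaults.yaml")
        return cls(
            p_minus=cfg["p_minus"],
            p_plus=cfg["p_plus"],
            cycles=cfg["cycles"],
            length_scaling=cfg["length_scaling"],
            reference_cag=cfg["reference_cag"],
        )


@dataclass
class MosaicismModel:
    """Template-pool somatic mosaicism: fraction of input molecules carrying
    ``inherited + i`` CAG, for offsets i = +1..+10."""

    expansion_freqs: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, f in self.expansion_freqs.items():
            if i < 1 or i > 10:
                raise ValueError("expansion offsets must be in +1..+10")
            if f < 0:
                raise ValueError("expansion fractions must be >= 0")
        if sum(self.expansion_freqs.values()) > 1:
            raise ValueError("expansion fractions must sum to <= 1")

    @property
    def total_fraction(self) -> float:
        return sum(self.expansion_freqs.values())

    @property
    def true_ratio(self) -> float:
        """Expected expansion ratio of the template pool itself,
        sum(f_i) / (1 - sum(f_i))."""
        s = self.total_fraction
        return s / (1.0 - s)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded alongside emitted reads."""

    template_counts: dict[int, int]          # template cag -> input molecules
    read_origin_counts: dict[tuple[int, int], int]  # (template cag, net slip) -> reads
    true_template_ratio: float               # mosaicism of the template pool
    expected_measured_ratio: float | None    # incl. PCR stutter + error filter
    seed: int

    def n_reads(self) -> int:
        return sum(self.read_origin_counts.values())


@dataclass
class ReadSet:
    """Simulated reads plus their ground truth."""

    reads: list[tuple[str, str]]             # (read_id, sequence)
    truth: SimTruth
    length_counts: dict[tuple[str, int], int]  # (variant_tag, emitted cag) -> reads

    def write_fastq(self, path) -> None:
        """Plain or gzipped FASTQ, constant Q40 qualities."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for read_id, seq in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Exact expectation of the branching process
# ---------------------------------------------------------------------------

_PAD = 14  # +-14 units of slip head-room; deeper net slips are negligible


def expected_pool_distribution(
    template_weights: Mapping[int, float], params: StutterParams
) -> dict[int, float]:
    """Exact expected product-length distribution of the branching PCR.

    ``template_weights`` maps template cag -> input weight (molecule counts
    or fractions).  Returns cag -> expected fraction of the final pool.
    """
    lo = min(template_weights) - _PAD
    hi = max(template_weights) + _PAD
    lengths = np.arange(max(lo, 1), hi + 1)
    v = np.zeros(len(lengths), dtype=float)
    for cag, w in template_weights.items():
        v[int(cag - lengths[0])] = w
    pm, pp = params.slip_probs(lengths)
    stay = 1.0 - pm - pp
    for _ in range(params.cycles):
        nxt = v + v * stay
        nxt[:-1] += (v * pm)[1:]   # copy of L lands at L-1
        nxt[1:] += (v * pp)[:-1]   # copy of L lands at L+1
        v = nxt
    v /= v.sum()
    return {int(L): float(x) for L, x in zip(lengths, v) if x > 0}


def expected_measured_ratios(
    template_freqs: Mapping[int, float],
    inherited_cag: int,
    params: StutterParams,
    error_rate: float = 0.001,
    window: int = 10,
) -> dict[int, float]:
    """Expected per-offset measured ratios R_i = E[reads at inherited+i] /
    E[reads at inherited], i = 1..window, after PCR stutter and the
    sequencing-error decomposition filter.

    A substitution inside the repeat region breaks exact unit decomposition,
    so the pass probability of a read at length L is proportional to
    ``(1 - error_rate) ** (3 L)``; only the relative factor across offsets
    matters here.
    """
    pool = expected_pool_distribution(template_freqs, params)
    keep = (1.0 - error_rate) ** 3
    base = pool.get(inherited_cag, 0.0)
    if base <= 0:
        raise ValueError("no expected mass at the inherited length")
    return {
        i: pool.get(inherited_cag + i, 0.0) * keep**i / base
        for i in range(1, window + 1)
    }


def calibrate_p_plus(
    target_plus1_ratio: float = 0.023,
    template_cag: int = 33,
    p_minus: float = 0.01,
    cycles: int = 30,
    length_scaling: float = 1.05,
    error_rate: float = 0.001,
) -> float:
    """Solve for the per-cycle forward slip probability that makes the
    single-molecule assay's expected +1/inherited read ratio hit the target."""
    from scipy.optimize import brentq

    def f(p_plus: float) -> float:
        params = StutterParams(p_minus=p_minus, p_plus=p_plus, cycles=cycles,
                               length_scaling=length_scaling,
                               reference_cag=template_cag)
        r = expected_measured_ratios({template_cag: 1.0}, template_cag, params,
                                     error_rate=error_rate)
        return r[1] - target_plus1_ratio

    return float(brentq(f, 1e-7, 0.05, xtol=1e-12))


def solve_template_freqs(
    target_measured_ratios: Mapping[int, float],
    inherited_cag: int,
    params: StutterParams,
    error_rate: float = 0.001,
    n_iter: int = 25,
) -> dict[int, float]:
    """Invert measured-ratio targets into template-pool expansion fractions.

    Measured per-offset ratios include the PCR-stutter contribution; this
    fixed-point iteration finds template per-offset ratios t_i (relative to
    the inherited template class) such that the exact expectation of the full
    assay reproduces the targets, then converts to pool fractions.
    """
    offsets = sorted(target_measured_ratios)
    target = np.array([target_measured_ratios[i] for i in offsets])
    t = target.copy()
    for _ in range(n_iter):
        weights = {inherited_cag: 1.0}
        for i, ti in zip(offsets, t):
            weights[inherited_cag + i] = max(float(ti), 0.0)
        got = expected_measured_ratios(weights, inherited_cag, params, error_rate)
        r = np.array([got[i] for i in offsets])
        t = np.maximum(t + (target - r), 0.0)
    denom = 1.0 + t.sum()
    freqs = {i: float(ti / denom) for i, ti in zip(offsets, t) if ti > 0}
    if any(f < 0 for f in freqs.values()):
        raise ValueError("targets below the pure-stutter baseline are infeasible")
    return freqs


# ---------------------------------------------------------------------------
# Stochastic simulation
# ---------------------------------------------------------------------------


def simulate_pcr_pool(
    template_counts: Mapping[int, int],
    params: StutterParams,
    rng: np.random.Generator,
) -> dict[tuple[int, int], int]:
    """Branching amplification of a template pool, tracking molecule origin.

    Returns (template cag, current cag) -> molecule count after
    ``params.cycles`` cycles.
    """
    pool: dict[tuple[int, int], int] = {
        (int(c), int(c)): int(n) for c, n in template_counts.items() if n > 0
    }
    for _ in range(params.cycles):
        new: dict[tuple[int, int], int] = {}
        for (orig, cur), m in sorted(pool.items()):
            pm, pp = params.slip_probs(cur)
            down, up, stay = rng.multinomial(m, [float(pm), float(pp), 1.0 - float(pm) - float(pp)])
            for cag, k in ((cur - 1, down), (cur + 1, up), (cur, stay)):
                if k and cag >= 1:
                    key = (orig, cag)
                    new[key] = new.get(key, 0) + int(k)
        for key, k in new.items():
            pool[key] = pool.get(key, 0) + k
    return pool


def _mutate(seq_bytes: np.ndarray, n_err: int, rng: np.random.Generator) -> str:
    out = seq_bytes.copy()
    pos = rng.choice(len(out), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out.tobytes().decode()


def _emit_reads(
    class_counts: Sequence[tuple[AlleleStructure, int, int, int]],
    error_rate: float,
    rng: np.random.Generator,
    read_prefix: str,
    anchors: tuple[str, str] = (DEFAULT_ANCHOR_5P, DEFAULT_ANCHOR_3P),
) -> tuple[list[tuple[str, str]], dict[tuple[int, int], int], dict[tuple[str, int], int]]:
    """Render reads for (structure, template_cag, current_cag, count) classes."""
    a5, a3 = anchors
    reads: list[tuple[str, str]] = []
    origin_counts: dict[tuple[int, int], int] = {}
    length_counts: dict[tuple[str, int], int] = {}
    idx = 0
    for structure, orig, cur, count in class_counts:
        amplicon = a5 + structure.to_sequence() + a3
        base = np.frombuffer(amplicon.encode(), dtype=np.uint8)
        n_err = rng.binomial(len(amplicon), error_rate, size=count)
        for k in n_err:
            rid = f"{read_prefix}:{idx}"
            idx += 1
            seq = amplicon if k == 0 else _mutate(base, int(k), rng)
            reads.append((rid, seq))
        key = (orig, cur - orig)
        origin_counts[key] = origin_counts.get(key, 0) + count
        lkey = (structure.variant_tag, cur)
        length_counts[lkey] = length_counts.get(lkey, 0) + count
    return reads, origin_counts, length_counts


def _sample_reads_from_pool(
    pools: Sequence[tuple[AlleleStructure, dict[tuple[int, int], int]]],
    depth: int,
    rng: np.random.Generator,
) -> list[tuple[AlleleStructure, int, int, int]]:
    """Multinomial read sampling across all pool classes (pool >> depth)."""
    keys: list[tuple[AlleleStructure, int, int]] = []
    weights: list[float] = []
    for structure, pool in pools:
        for (orig, cur), m in sorted(pool.items()):
            keys.append((structure.with_cag(cur), orig, cur))
            weights.append(float(m))
    w = np.array(weights)
    counts = rng.multinomial(depth, w / w.sum())
    return [
        (s, orig, cur, int(c))
        for (s, orig, cur), c in zip(keys, counts)
        if c > 0
    ]


def simulate_molecule_pcr(
    template: AlleleStructure,
    params: StutterParams,
    n_reads: int,
    seed: int,
    error_rate: float = 0.001,
    sample_id: str = "single-molecule",
) -> ReadSet:
    """Single-molecule assay: one input molecule, no somatic mosaicism.

    The emitted read-length distribution reflects PCR stutter alone, which is
    what the single-molecule benchmark isolates.
    """
    rng = np.random.default_rng(seed)
    pool = simulate_pcr_pool({template.cag: 1}, params, rng)
    classes = _sample_reads_from_pool([(template, pool)], n_reads, rng)
    reads, origin_counts, length_counts = _emit_reads(
        classes, error_rate, rng, read_prefix=sample_id)
    expected = expected_measured_ratios({template.cag: 1.0}, template.cag,
                                        params, error_rate)
    truth = SimTruth(
        template_counts={template.cag: 1},
        read_origin_counts=origin_counts,
        true_template_ratio=0.0,
        expected_measured_ratio=float(sum(expected.values())),
        seed=seed,
    )
    return ReadSet(reads=reads, truth=truth, length_counts=length_counts)


def simulate_tissue_reads(
    inherited: tuple[AlleleStructure, AlleleStructure],
    mosaicism: MosaicismModel,
    params: StutterParams,
    depth: int,
    seed: int,
    n_templates: int = 200_000,
    error_rate: float = 0.001,
    sample_id: str = "tissue",
) -> ReadSet:
    """Bulk tissue assay: heterozygous template pool with expansion-biased
    somatic mosaicism on the longer allele, then bulk PCR stutter.

    The template pool defaults to 2e5 molecules so template-sampling noise is
    small relative to read-sampling noise at typical depths.
    """
    if depth < 100:
        raise ValueError("depth < 100 reads gives an unreliable ratio; refusing")
    short, long_ = inherited
    rng = np.random.default_rng(seed)
    n_long = n_templates // 2
    n_short = n_templates - n_long
    offsets = sorted(mosaicism.expansion_freqs)
    probs = [mosaicism.expansion_freqs[i] for i in offsets]
    probs.append(1.0 - sum(probs))
    counts = rng.multinomial(n_long, probs)
    long_templates = {long_.cag + i: int(c) for i, c in zip(offsets, counts[:-1]) if c}
    long_templates[long_.cag] = long_templates.get(long_.cag, 0) + int(counts[-1])
    pool_long = simulate_pcr_pool(long_templates, params, rng)
    pool_short = simulate_pcr_pool({short.cag: n_short}, params, rng)
    classes = _sample_reads_from_pool(
        [(long_, pool_long), (short, pool_short)], depth, rng)
    reads, origin_counts, length_counts = _emit_reads(
        classes, error_rate, rng, read_prefix=sample_id)
    template_freqs = {long_.cag: 1.0 - mosaicism.total_fraction}
    for i in offsets:
        template_freqs[long_.cag + i] = mosaicism.expansion_freqs[i]
    expected = expected_measured_ratios(template_freqs, long_.cag, params, error_rate)
    template_counts = dict(long_templates)
    template_counts[short.cag] = template_counts.get(short.cag, 0) + n_short
    truth = SimTruth(
        template_counts=template_counts,
        read_origin_counts=origin_counts,
        true_template_ratio=mosaicism.true_ratio,
        expected_measured_ratio=float(sum(expected.values())),
        seed=seed,
    )
    return ReadSet(reads=reads, truth=truth, length_counts=length_counts)


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortCoeffs:
    """Generating linear model for a cohort's expansion ratios."""

    intercept: float
    beta_cag: float
    beta_age: float
    beta_interaction: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for v in (self.intercept, self.beta_cag, self.beta_age, self.beta_interaction):
            if not np.isfinite(v):
                raise ValueError("coefficients must be finite")


def simulate_cohort(
    category: str,
    n_samples: int,
    coeffs: CohortCoeffs,
    cag_range: tuple[int, int],
    age_range: tuple[float, float] = (20.0, 90.0),
    seed: int = 0,
    group: str = "unknown",
    id_prefix: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cohort table of per-sample expansion ratios on a linear CAG x age model.

    CAG is uniform on the category's integer range, age uniform on
    ``age_range``; ratio = intercept + b_cag*CAG + b_age*age
    + b_int*CAG*age + N(0, noise_sd), truncated at 0 (ratios are
    nonnegative by construction).
    """
    if cag_range[0] > cag_range[1] or age_range[0] >= age_range[1]:
        raise ValueError("covariate ranges must be non-degenerate")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or category[:2].upper()
    cag = rng.integers(cag_range[0], cag_range[1] + 1, size=n_samples)
    # ages are stored to 0.01 y; the plane uses the stored values so
    # noise-free cohorts sit exactly on a refittable plane
    age = np.round(rng.uniform(age_range[0], age_range[1], size=n_samples), 2)
    plane = (coeffs.intercept + coeffs.beta_cag * cag + coeffs.beta_age * age
             + coeffs.beta_interaction * cag * age)
    ratio = np.maximum(plane + rng.normal(0.0, coeffs.noise_sd, size=n_samples), 0.0)
    table = pd.DataFrame({
        "sample_id": [f"{prefix}{i:04d}" for i in range(n_samples)],
        "inherited_cag": cag.astype(int),
        "age_at_sampling": age,
        "category": category,
        "group": group,
        "ratio": ratio,
    })
    truth = {
        "coeffs": coeffs,
        "expected_ratio": plane,
        "seed": seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Shipped scenarios
# ---------------------------------------------------------------------------


def load_scenario(name: str) -> dict:
    """Load a shipped scenario description by name (without extension)."""
    ref = importlib.resources.files("cagmosaic") / "scenarios" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def scenario_cohort(scenario: dict, seed: int) -> tuple[pd.DataFrame, dict]:
    """Run a cohort-type scenario (possibly multi-group) at a given seed."""
    frames = []
    truths = {}
    groups = scenario.get("groups") or [scenario]
    for k, g in enumerate(groups):
        coeffs = CohortCoeffs(**g["coeffs"])
        table, truth = simulate_cohort(
            category=g.get("category", scenario.get("category", "intermediate")),
            n_samples=g["n_samples"],
            coeffs=coeffs,
            cag_range=tuple(g["cag_range"]),
            age_range=tuple(g.get("age_range", (20.0, 90.0))),
            seed=seed + k,
            group=g.get("group", "unknown"),
            id_prefix=g.get("id_prefix"),
        )
        frames.append(table)
        truths[g.get("group", f"group{k}")] = truth
    return pd.concat(frames, ignore_index=True), truths


def scenario_tissue_readsets(
    scenario: dict,
    seed: int,
    depth: int | None = None,
    error_rate: float | None = None,
) -> dict[str, ReadSet]:
    """Run a tissue-panel scenario: one read set per tissue.

    Per-tissue targets are MEASURED per-offset ratios (they include the PCR
    stutter baseline, as the printed values do); template expansion
    frequencies are derived by inverting the stutter expectation model.
    """
    params = StutterParams(**scenario["stutter"]) if "stutter" in scenario \
        else StutterParams.calibrated_default()
    error_rate = scenario.get("error_rate", 0.001) if error_rate is None else error_rate
    depth = depth or scenario["depth"]
    short = AlleleStructure(**scenario["allele_short"])
    long_ = AlleleStructure(**scenario["allele_long"])
    out: dict[str, ReadSet] = {}
    for k, (tissue, targets) in enumerate(sorted(scenario["tissues"].items())):
        measured = {int(i): float(r) for i, r in targets["measured_ratios"].items()}
        freqs = solve_template_freqs(measured, long_.cag, params, error_rate)
        model = MosaicismModel(expansion_freqs=freqs)
        out[tissue] = simulate_tissue_reads(
            (short, long_), model, params, depth=depth,
            seed=(seed * 1009 + k) % 2**31, error_rate=error_rate,
            n_templates=scenario.get("n_templates", 200_000),
            sample_id=tissue,
        )
    return out


def scenario_single_molecule(scenario: dict, seed: int,
                             n_reads: int | None = None) -> ReadSet:
    params = StutterParams(**scenario["stutter"]) if "stutter" in scenario \
        else StutterParams.calibrated_default()
    template = AlleleStructure(**scenario["template"])
    return simulate_molecule_pcr(
        template, params,
        n_reads=n_reads or scenario["n_reads"],
        seed=seed,
        error_rate=scenario.get("error_rate", 0.001),
    )
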