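"""Format plumbing: FASTQ input, provenance-headed TSV/JSON outputs.

Every data file the pipeline writes starts with ``#``-prefixed provenance
lines (tool version, config hash, seed) so outputs are diff-able and
bit-stable; readers skip those lines.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .mosaicism import ExpansionProfile
from .repeat_genotyper import SampleGenotype

SCHEMA_VERSION = 1


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a plain or gzipped FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield record.id, str(record.seq)


def config_hash(config: dict | None) -> str:
    payload = yaml.safe_dump(config or {}, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_lines(config: dict | None = None, seed: int | None = None) -> list[str]:
    return [
        f"# cagmosaic v{__version__} schema={SCHEMA_VERSION}",
        f"# config_sha={config_hash(config)} seed={seed}",
    ]


def write_tsv(frame: pd.DataFrame, path, config: dict | None = None,
              seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_lines(config, seed):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj: dict, path, config: dict | None = None,
               seed: int | None = None) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool": f"cagmosaic v{__version__}",
        "config_sha": config_hash(config),
        "seed": seed,
        **obj,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


def histogram_frame(sample_id: str, genotype: SampleGenotype) -> pd.DataFrame:
    rows = [
        {"sample_id": sample_id, "variant_tag": tag, "cag": cag, "reads": count}
        for (tag, cag), count in sorted(genotype.histogram_by_structure.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "variant_tag", "cag", "reads"])


def genotype_frame(sample_id: str, genotype: SampleGenotype) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": sample_id,
        "allele_short_cag": genotype.allele_short.cag,
        "allele_short_tag": genotype.allele_short.variant_tag,
        "allele_long_cag": genotype.allele_long.cag,
        "allele_long_tag": genotype.allele_long.variant_tag,
        "total_pass_reads": genotype.total_pass_reads,
    }])


def profiles_frame(
    profiles: list[tuple[ExpansionProfile, bool, str, bool | None]],
) -> pd.DataFrame:
    """Rows of (profile, eligible, reason, genuine_flag)."""
    rows = []
    for profile, eligible, reason, genuine in profiles:
        row = {
            "sample_id": profile.sample_id,
            "tissue": profile.tissue,
            "allele_role": profile.allele_role,
            "variant_tag": profile.variant_tag,
            "inherited_cag": profile.inherited_cag,
            "n": profile.n,
        }
        for i, c in enumerate(profile.n_plus, start=1):
            row[f"n_plus_{i}"] = c
        row.update(ratio=profile.ratio, eligible=eligible,
                   eligibility_reason=reason, genuine=genuine)
        rows.append(row)
    return pd.DataFrame(rows)
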