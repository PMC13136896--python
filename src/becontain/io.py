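"""Tabular and config I/O for screen results, spot counts and schemes.

Candidate tables are TSV with the documented column set; protospacers can
also be written as 6-column BED (0-based half-open, strand in column 6).
Dilution schemes round-trip through small YAML/JSON config files, and assay
results are emitted as a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .assay_quant import DilutionScheme, SpotObservation
from .be_screen import GuideCandidate, ScreenResult

CANDIDATE_COLUMNS = [
    "gene_id", "spacer", "pam", "chrom_start", "chrom_end", "strand",
    "target_c_offset", "n_bystanders", "bystander_regions",
    "predicted_start_codon", "score", "eligibility",
]


def candidates_to_frame(
    candidates: Sequence[GuideCandidate] | ScreenResult,
) -> pd.DataFrame:
    if isinstance(candidates, ScreenResult):
        candidates = candidates.candidates
    rows = []
    for c in candidates:
        rows.append({
            "gene_id": c.gene_id,
            "spacer": c.spacer,
            "pam": c.pam,
            "chrom_start": c.protospacer_start,
            "chrom_end": c.protospacer_end,
            "strand": c.protospacer_strand,
            "target_c_offset": c.target_c_offset,
            "n_bystanders": len(c.bystanders),
            "bystander_regions": ",".join(b.region for b in c.bystanders),
            "predicted_start_codon": c.predicted_start_codon,
            "score": "" if c.on_target_score is None else c.on_target_score,
            "eligibility": c.eligibility,
        })
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates_tsv(
    candidates: Sequence[GuideCandidate] | ScreenResult, path: str | Path
) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_candidates_bed(
    candidates: Sequence[GuideCandidate] | ScreenResult,
    genome_id: str, path: str | Path,
) -> None:
    if isinstance(candidates, ScreenResult):
        candidates = candidates.candidates
    with open(path, "w") as fh:
        for c in candidates:
            score = 0 if c.on_target_score is None else c.on_target_score
            fh.write(
                f"{genome_id}\t{c.protospacer_start}\t{c.protospacer_end}\t"
                f"{c.gene_id}|{c.spacer}\t{score}\t{c.protospacer_strand}\n"
            )


def write_spot_counts(obs: Iterable[SpotObservation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(o.condition, o.replicate, o.step, o.colony_count) for o in obs],
        columns=["condition", "replicate", "step", "count"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_spot_counts(path: str | Path) -> list[SpotObservation]:
    frame = pd.read_csv(path, sep="\t")
    return [
        SpotObservation(
            condition=str(r.condition),
            replicate=int(r.replicate),
            step=int(r.step),
            colony_count=int(r.count),
        )
        for r in frame.itertuples(index=False)
    ]


_SCHEME_FIELDS = [f.name for f in dataclasses.fields(DilutionScheme)]


def write_scheme(scheme: DilutionScheme, path: str | Path) -> None:
    data = dataclasses.asdict(scheme)
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh)


def read_scheme(path: str | Path) -> DilutionScheme:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    unknown = set(data) - set(_SCHEME_FIELDS)
    if unknown:
        raise ValueError(f"unknown scheme fields: {sorted(unknown)}")
    return DilutionScheme(**data)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(report: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")
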