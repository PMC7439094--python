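"""Readers and writers for the pipeline's plain-text formats.

* Abundance TSV: rows = samples (first column ``sample_id``), columns =
  metabolites; an empty cell means missing (below LOD).  No numeric
  sentinels.
* Metadata TSV: ``sample_id``, ``strain``, ``diet``, ``run_day`` and the
  optional ``vitd_25ohd`` / ``litter_size`` columns.
* GMT: one set per line — name, description, then tab-separated member ids.

Lines starting with ``#`` are comments; writers emit a provenance header
(package version, seed, config hash) that readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, StudyDesign, ValidationError


def _header(meta: Optional[dict]) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# ccmetab {parts}\n"


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------

def write_abundance(m: AbundanceMatrix, path, meta: Optional[dict] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        m.values.rename_axis("sample_id").to_csv(fh, sep="\t", na_rep="")


def read_abundance(path) -> pd.DataFrame:
    """Read an abundance TSV into a samples x metabolites DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in {path}: {dups}")
    if df.columns.has_duplicates:
        raise ValidationError(f"duplicate metabolite columns in {path}")
    return df.astype(float)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

def write_design(d: StudyDesign, path, meta: Optional[dict] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        d.table.rename_axis("sample_id").to_csv(fh, sep="\t", na_rep="")


def read_design(path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    return StudyDesign(df)


def build_matrix(values: pd.DataFrame, design: StudyDesign) -> AbundanceMatrix:
    """Attach run-day labels from the design to a raw value table."""
    if "run_day" not in design.table.columns:
        raise ValidationError("design lacks a run_day column")
    only_m = values.index.difference(design.sample_ids)
    only_d = design.sample_ids.difference(values.index)
    if len(only_m) or len(only_d):
        raise ValidationError(
            "matrix/design sample mismatch: "
            f"only in matrix {only_m.tolist()}, only in design {only_d.tolist()}"
        )
    return AbundanceMatrix(
        values=values.loc[design.sample_ids],
        run_day=design.table["run_day"],
    )


def load_study(abundance_path, design_path) -> Tuple[AbundanceMatrix, StudyDesign]:
    design = read_design(design_path)
    values = read_abundance(abundance_path)
    return build_matrix(values, design), design


# ---------------------------------------------------------------------------
# GMT metabolite sets
# ---------------------------------------------------------------------------

def write_gmt(sets: Dict[str, Sequence[str]], path,
              descriptions: Optional[Dict[str, str]] = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    """Parse a GMT file; duplicate members within a set are dropped with a
    warning so set sizes count each metabolite once."""
    import warnings

    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *members = fields
            if name in sets:
                raise ValidationError(f"duplicate set name {name!r} in {path}")
            deduped = list(dict.fromkeys(m for m in members if m))
            if len(deduped) < len([m for m in members if m]):
                warnings.warn(
                    f"set {name!r}: duplicate members deduplicated",
                    UserWarning, stacklevel=2,
                )
            sets[name] = deduped
    return sets


# ---------------------------------------------------------------------------
# Generic table output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None,
                index_label: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, sep="\t", na_rep="", index_label=index_label)
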