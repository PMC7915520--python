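"""Readers and writers for the pipeline's plain-text formats.

Genotypes: lines x markers TSV with calls ``A`` (domesticated parent),
``B`` (wild parent) and ``NA``.  Maps: ``marker, chrom, cM`` TSV.
Phenotypes: long TSV ``line, env, replicate, trait, value``.  Effects
and loci round-trip through JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import QTLEffect, QTLLocus

MISSING = "NA"


def write_genotypes(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, sep="\t", index_label="line", na_rep=MISSING)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="line",
                     na_values=[MISSING], keep_default_na=True, dtype=str)
    return df


def write_map(map_df: pd.DataFrame, path) -> None:
    map_df.to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    need = {"line", "env", "replicate", "trait", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(need)}")
    return df


def write_effects(effects: Iterable[QTLEffect], path) -> None:
    Path(path).write_text(json.dumps([e.to_dict() for e in effects],
                                     indent=1, sort_keys=True))


def read_effects(path) -> list[QTLEffect]:
    return [QTLEffect.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_loci(loci: Sequence[QTLLocus], path) -> None:
    Path(path).write_text(json.dumps([l.to_dict() for l in loci],
                                     indent=1, sort_keys=True))


def read_loci(path) -> list[QTLLocus]:
    return [QTLLocus.from_dict(d) for d in json.loads(Path(path).read_text())]


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
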