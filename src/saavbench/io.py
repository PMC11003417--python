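"""Shared readers/writers and configuration loading.

FASTA goes through Biopython (plain or gzip); tables are tab-separated
UTF-8 with a header row, read and written with pandas so round trips are
stable.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, List, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> List[Tuple[str, str]]:
    """Read (id, sequence) records from a FASTA file (``.gz`` supported)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration; referenced ``*_path`` values must exist."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    for key, value in data.items():
        if key.endswith("_path") and not Path(str(value)).exists():
            raise ConfigError(f"{path}: {key} refers to a missing file: {value}")
    return data


def set_up_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
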