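"""Readers and writers for the pipeline's delimited-text artifacts.

Formats (TSV by default, comma selectable everywhere via ``sep``):

* beta matrix — first column ``probe_id``, one column per sample;
* sample sheet — one row per sample with the SampleTable columns;
* annotation manifest — one row per probe, BED export available;
* clock file — a ``#ooclock-clock-v1`` JSON header line followed by a
  probe/weight table, so one text file round-trips a full Clock;
* EWAS table — probe-indexed statistics table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datamodel import BetaMatrix, Clock, CpGAnnotation, SampleTable, ValidationError
from .transforms import AgeTransform

CLOCK_MAGIC = "#ooclock-clock-v1"
FLOAT_FMT = "%.17g"  # lossless for float64


def read_beta_matrix(path, sep: str = "\t") -> BetaMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = "probe_id"
    return BetaMatrix(df)


def write_beta_matrix(betas: BetaMatrix, path, sep: str = "\t") -> None:
    df = betas.df.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT)


def read_sample_sheet(path, sep: str = "\t") -> SampleTable:
    return SampleTable(pd.read_csv(path, sep=sep))


def write_sample_sheet(samples: SampleTable, path, sep: str = "\t") -> None:
    samples.df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_annotation(path, sep: str = "\t") -> CpGAnnotation:
    return CpGAnnotation(pd.read_csv(path, sep=sep))


def write_annotation(annotation: CpGAnnotation, path, sep: str = "\t") -> None:
    annotation.df.to_csv(path, sep=sep, index=False)


def annotation_to_bed(annotation: CpGAnnotation, path) -> None:
    """BED-compatible export: chromosome, position−1, position, probe_id."""
    df = annotation.df
    bed = pd.DataFrame(
        {
            "chrom": df["chromosome"],
            "start": df["position"] - 1,
            "end": df["position"],
            "name": df["probe_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_clock(clock: Clock, path) -> None:
    header = {
        "transform": clock.transform.to_dict(),
        "intercept": clock.intercept,
        "metadata": clock.metadata,
    }
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{CLOCK_MAGIC}\t{json.dumps(header)}\n")
        fh.write("probe_id\tweight\n")
        for probe, w in clock.coefficients.items():
            fh.write(f"{probe}\t{w:.17g}\n")


def read_clock(path) -> Clock:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(CLOCK_MAGIC):
            raise ValidationError(f"{path} is not a clock file (missing header)")
        header = json.loads(first.split("\t", 1)[1])
        table = pd.read_csv(fh, sep="\t")
    coefficients = dict(zip(table["probe_id"].astype(str), table["weight"].astype(float)))
    return Clock(
        transform=AgeTransform.from_dict(header["transform"]),
        intercept=float(header["intercept"]),
        coefficients=coefficients,
        metadata=header.get("metadata", {}),
    )


def write_ewas(ewas: pd.DataFrame, path, sep: str = "\t") -> None:
    out = ewas.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep, float_format=FLOAT_FMT)


def read_ewas(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df
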