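"""Readers and writers for the package's interchange files.

Trace data travels as tab-separated text with the header
``well_id  channel  time_s  fluorescence`` (one row per reading); chip layouts
and threshold sets as YAML; paired calls and 2x2 count tables as TSV/YAML.
All writers format floats explicitly so that a fixed seed produces
byte-identical files, and all readers report malformed rows with their line
number.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assay_model import (
    CHANNELS,
    AssayModelError,
    FluorescenceTrace,
    ThresholdSet,
    WellAssay,
)
from .concordance import ConcordanceTable, ConcordanceError
from .genotyper import SampleGenotype

TRACE_COLUMNS = ["well_id", "channel", "time_s", "fluorescence"]


class SchemaError(ValueError):
    """File does not conform to its documented schema."""


def read_traces(path) -> list[FluorescenceTrace]:
    """Parse a trace TSV into one :class:`FluorescenceTrace` per well-channel."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != TRACE_COLUMNS:
        raise SchemaError(f"{path}: expected columns {TRACE_COLUMNS}, got {list(df.columns)}")
    for col in ("time_s", "fluorescence"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
    neg = df.index[df["time_s"].astype(float) < 0]
    if len(neg):
        raise SchemaError(f"{path}: negative time at line {neg[0] + 2}")
    traces = []
    for (well, channel), grp in df.groupby(["well_id", "channel"], sort=True):
        try:
            traces.append(
                FluorescenceTrace(
                    int(well),
                    str(channel),
                    grp["time_s"].to_numpy(float),
                    grp["fluorescence"].to_numpy(float),
                )
            )
        except AssayModelError as exc:
            raise SchemaError(f"{path}: well {well} channel {channel}: {exc}") from exc
    return traces


def write_traces(traces: Iterable[FluorescenceTrace], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for tr in traces:
            for t, v in zip(tr.times, tr.values):
                fh.write(f"{tr.well_id}\t{tr.channel}\t{t:.1f}\t{v:.4f}\n")


def read_thresholds(path) -> dict[tuple[int, str], ThresholdSet]:
    """Threshold YAML -> {(well_id, channel): ThresholdSet}.

    Schema: optional ``defaults`` mapping (EP, JP, FNT, RPT) plus ``wells:
    {well_id: {channel: {...overrides...}}}``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: thresholds file must be a mapping")
    defaults = dict(doc.get("defaults") or {})
    out: dict[tuple[int, str], ThresholdSet] = {}
    for well_id, channels in (doc.get("wells") or {}).items():
        for channel, params in channels.items():
            if channel not in CHANNELS:
                raise SchemaError(f"{path}: unknown channel {channel!r} for well {well_id}")
            merged = {**defaults, **(params or {})}
            try:
                out[(int(well_id), channel)] = ThresholdSet(**merged)
            except (TypeError, AssayModelError) as exc:
                raise SchemaError(f"{path}: well {well_id}/{channel}: {exc}") from exc
    if not out:
        raise SchemaError(f"{path}: no well thresholds defined")
    return out


def write_thresholds(thresholds: Mapping[tuple[int, str], ThresholdSet], path) -> None:
    wells: dict[int, dict[str, dict]] = {}
    for (well_id, channel), ts in sorted(thresholds.items()):
        wells.setdefault(well_id, {})[channel] = {
            "EP": round(float(ts.EP), 4),
            "JP": round(float(ts.JP), 4),
            "FNT": round(float(ts.FNT), 6),
            "RPT": round(float(ts.RPT), 6),
        }
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump({"wells": wells}, fh, sort_keys=True)


CALL_COLUMNS = ["sample", "well_id", "target", "F_EP", "F_JP", "SR", "status", "reason"]


def write_calls(genotypes: Sequence[SampleGenotype], path) -> None:
    """Per-well call TSV: mutant-channel quantities plus the well decision."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for g in genotypes:
            for wc in g.calls:
                mc = wc.mutant_channel_call
                sr = "" if mc.sr is None else f"{mc.sr:.4f}"
                target = "" if wc.target is None else str(wc.target)
                fh.write(
                    f"{g.sample_id}\t{wc.well_id}\t{target}\t{mc.f_ep:.4f}\t{mc.f_jp:.4f}"
                    f"\t{sr}\t{wc.mutation_status.value}\t{mc.reason.value}\n"
                )


def write_genotype_summary(genotypes: Sequence[SampleGenotype], path) -> None:
    doc = [
        {
            "sample": g.sample_id,
            "overall": g.overall.value,
            "detected_mutations": sorted(str(m) for m in g.detected_mutations),
        }
        for g in genotypes
    ]
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_tables(path) -> dict[str, ConcordanceTable]:
    """2x2 count tables from YAML: ``tables: {name: {a: .., b: .., c: .., d: ..}}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "tables" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'tables' key")
    out = {}
    for name, cells in doc["tables"].items():
        try:
            out[name] = ConcordanceTable(**{k: int(cells[k]) for k in "abcd"})
        except (KeyError, ConcordanceError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: table {name!r}: {exc}") from exc
    return out


PAIRED_COLUMNS = ["sample", "gene", "method", "call"]


def read_paired_calls(
    path, method_a: str = "AMDS", method_b: str = "DS"
) -> tuple[dict[str, ConcordanceTable], dict[str, int]]:
    """Long-format paired calls TSV -> per-gene 2x2 tables.

    Samples lacking a call from either method for a gene are excluded from that
    gene's table; the per-gene excluded counts are returned alongside so the
    exclusion is always visible (sequencing failures are data, not noise).
    """
    from .concordance import build_table

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != PAIRED_COLUMNS:
        raise SchemaError(f"{path}: expected columns {PAIRED_COLUMNS}, got {list(df.columns)}")
    tables: dict[str, ConcordanceTable] = {}
    excluded: dict[str, int] = {}
    for gene, grp in df.groupby("gene", sort=True):
        wide = grp.pivot_table(index="sample", columns="method", values="call", aggfunc="first")
        for m in (method_a, method_b):
            if m not in wide.columns:
                wide[m] = np.nan
        complete = wide.dropna(subset=[method_a, method_b])
        excluded[gene] = len(wide) - len(complete)
        try:
            tables[gene] = build_table(list(complete[method_a]), list(complete[method_b]))
        except ConcordanceError as exc:
            raise SchemaError(f"{path}: gene {gene}: {exc}") from exc
    return tables, excluded


def write_layout(wells: Sequence[WellAssay], path) -> None:
    from .assay_model import serialize_chip_layout

    Path(path).write_text(serialize_chip_layout(wells), newline="\n")
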