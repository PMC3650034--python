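"""Seeded generation of a self-consistent synthetic fixture bundle.

Everything the pipeline consumes can be generated from one integer seed: a
full chip layout (13 test wells plus controls), calibration runs (no-template,
wild-type-only, 5%-mutant), the thresholds calibrated from them, a
mutant-fraction x template-mass titration trace set, paired-call tables whose
per-gene 2x2 counts equal the published clinical tables, and clone-sequencing
tallies.  Bundles are byte-identical under a fixed seed.

The paired-call and clone-set files carry real published *margins* but
synthetic per-sample assignments; filenames and docstrings say so.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from .assay_model import MutationTarget, ThresholdSet, WellAssay, panel_targets
from .clinical_data import (
    CLONE_INSERT_LENGTHS,
    FFPE_TABLES,
    FROZEN_TABLES,
    POLYMERASE_ER_RANGES,
)
from .io_files import write_layout, write_thresholds, write_traces
from .kinetics_sim import KineticsScenario, calibrate_thresholds, simulate_trace

TITRATION_FRACTIONS = (0.0, 0.005, 0.01, 0.05, 0.25, 0.5, 1.0)
TITRATION_MASSES_FG = (1.0, 10.0, 100.0)
CALIBRATION_REPLICATES = 8
TITRATION_REPLICATES = 3


def default_chip_layout() -> list[WellAssay]:
    """13 test wells (one per panel mutation, F1 = mutant) plus two controls."""
    wells = [
        WellAssay(
            well_id=i + 1,
            role="test",
            target=target,
            channel_allele_map={"F1": "mutant", "F2": "wild_type"},
        )
        for i, target in enumerate(panel_targets())
    ]
    wells.append(WellAssay(well_id=14, role="negative_control"))
    wells.append(WellAssay(well_id=15, role="positive_control"))
    return wells


def _write_calibration(out_dir: Path, scenario: KineticsScenario, seed: int) -> None:
    """One trace file + design file covering the three calibration classes."""
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3 * CALIBRATION_REPLICATES)]
    classes = [("no_template", None), ("0pct", 0.0), ("5pct", 0.05)]
    traces, design_rows = [], []
    well = 1
    for ci, (label, fraction) in enumerate(classes):
        for r in range(CALIBRATION_REPLICATES):
            if label == "no_template":
                scen = replace(scenario, template_mass_fg=0.0, carrier_genomic_mass_ng=0.0)
            else:
                scen = replace(scenario, mutant_fraction=fraction)
            mt, wt = simulate_trace(scen, well_id=well, rng=rngs[ci * CALIBRATION_REPLICATES + r])
            traces.extend([mt, wt])
            design_rows.append((well, label, "KRAS", "G13D"))
            well += 1
    write_traces(traces, out_dir / "calibration_traces.tsv")
    with open(out_dir / "calibration_design.tsv", "w", newline="\n") as fh:
        fh.write("well_id\tclass\tgene\tprotein_change\n")
        for row in design_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_titration(out_dir: Path, scenario: KineticsScenario, seed: int) -> None:
    tit_dir = out_dir / "titration"
    tit_dir.mkdir(exist_ok=True)
    ss = np.random.SeedSequence(seed)
    n = len(TITRATION_FRACTIONS) * len(TITRATION_MASSES_FG) * TITRATION_REPLICATES
    child = iter(ss.spawn(n))
    for f in TITRATION_FRACTIONS:
        for m in TITRATION_MASSES_FG:
            traces = []
            for r in range(TITRATION_REPLICATES):
                scen = replace(scenario, mutant_fraction=f, template_mass_fg=m)
                mt, wt = simulate_trace(scen, well_id=r + 1, rng=np.random.default_rng(next(child)))
                traces.extend([mt, wt])
            stem = f"f{f:g}_m{m:g}fg".replace(".", "p")
            write_traces(traces, tit_dir / f"{stem}.tsv")


def _write_sample_traces(out_dir: Path, scenario: KineticsScenario, seed: int) -> None:
    """A full-chip sample: every test well wild-type-only except a 25% G13D well."""
    layout = default_chip_layout()
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(len(layout)))
    traces = []
    for w in layout:
        if w.role != "test":
            continue
        is_g13d = w.target == MutationTarget("KRAS", "G13D")
        scen = replace(scenario, target=w.target, mutant_fraction=0.25 if is_g13d else 0.0)
        mt, wt = simulate_trace(scen, well_id=w.well_id, rng=np.random.default_rng(next(child)))
        traces.extend([mt, wt])
    write_traces(traces, out_dir / "sample_g13d_traces.tsv")


def _write_paired_calls(out_dir: Path) -> None:
    """Long-format paired calls whose per-gene 2x2 counts equal the published tables.

    Sample identities are synthetic; only the counts are factual.
    """
    for label, prefix, tables in (
        ("frozen", "FRZ", FROZEN_TABLES),
        ("ffpe", "FFPE", FFPE_TABLES),
    ):
        path = out_dir / f"paired_calls_{label}_synthetic.tsv"
        with open(path, "w", newline="\n") as fh:
            fh.write("sample\tgene\tmethod\tcall\n")
            for gene, t in tables.items():
                cells = [("MT", "MT")] * t.a + [("MT", "WT")] * t.b
                cells += [("WT", "MT")] * t.c + [("WT", "WT")] * t.d
                for i, (a_call, b_call) in enumerate(cells):
                    sample = f"{prefix}{i:03d}"
                    fh.write(f"{sample}\t{gene}\tAMDS\t{a_call}\n")
                    fh.write(f"{sample}\t{gene}\tDS\t{b_call}\n")


def _write_clone_sets(out_dir: Path, seed: int) -> None:
    """Synthetic clone-sequencing tallies for 14 discordant samples.

    Insert lengths are the published amplicon lengths; clone counts and
    alteration counts are drawn to sit inside the published polymerase
    error-rate ranges.
    """
    rng = np.random.default_rng(seed)
    regions = list(CLONE_INSERT_LENGTHS.items())
    lo, hi = POLYMERASE_ER_RANGES["GoTaq"]
    with open(out_dir / "clone_sets_synthetic.tsv", "w", newline="\n") as fh:
        fh.write(
            "sample\tregion\tinsert_length\tn_clones_sequenced"
            "\tn_target_mutant_clones\tn_off_target_alterations\n"
        )
        for i in range(14):
            region, length = regions[i % len(regions)]
            n_clones = int(rng.integers(10, 21))
            n_mut = int(rng.integers(3, max(4, n_clones // 2)))
            er = rng.uniform(lo, hi)
            n_alt = int(round(er / 100 * length * n_clones))
            fh.write(f"DISC{i:02d}\t{region}\t{length}\t{n_clones}\t{n_mut}\t{n_alt}\n")


def generate_fixtures(seed: int, out_dir) -> dict:
    """Write the full fixture bundle; returns a manifest (also saved as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    layout = default_chip_layout()
    write_layout(layout, out / "chip_layout.yaml")

    scenario = KineticsScenario(target=MutationTarget("KRAS", "G13D"))
    ts = calibrate_thresholds(scenario, replicates=CALIBRATION_REPLICATES, seed=sub[0])
    thresholds = {
        (w.well_id, ch): ts for w in layout if w.role == "test" for ch in ("F1", "F2")
    }
    write_thresholds(thresholds, out / "thresholds.yaml")

    _write_calibration(out, scenario, sub[0])
    _write_titration(out, scenario, sub[1])
    _write_sample_traces(out, scenario, sub[3])
    _write_paired_calls(out)
    _write_clone_sets(out, sub[2])

    manifest = {
        "seed": seed,
        "files": sorted(
            [str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()] + ["manifest.json"]
        ),
        "titration_fractions": list(TITRATION_FRACTIONS),
        "titration_masses_fg": list(TITRATION_MASSES_FG),
        "thresholds": {"FNT": round(ts.FNT, 6), "RPT": round(ts.RPT, 6), "EP": ts.EP, "JP": ts.JP},
    }
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
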