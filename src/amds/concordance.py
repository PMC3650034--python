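"""Method-comparison statistics for paired mutation calls.

Covers the arithmetic used to validate the chip caller against direct Sanger
sequencing: 2x2 agreement tables, observed agreement and Cohen's kappa,
discordant-call tallies across gene panels, genotyping call rates, the
clone-sequencing error rate (polymerase misreads per sequenced base), an exact
binomial test that mutant clones in a discordant sample exceed polymerase
error, and a patient-level cohort summary (per-gene frequencies, co-mutations,
paired frozen/FFPE consistency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .assay_model import MutationTarget, PANEL_GENES
from .genotyper import SampleGenotype

MT, WT = "MT", "WT"


class ConcordanceError(ValueError):
    """Malformed paired-call input or degenerate table."""


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement counts between method A (rows) and method B (columns).

    a: mutant by both; b: mutant by A only; c: mutant by B only; d: wild-type
    by both.  In this package method A is the chip caller and method B the
    sequencing comparator.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConcordanceError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def observed_agreement(self) -> float:
        if self.n == 0:
            raise ConcordanceError("empty table")
        return (self.a + self.d) / self.n

    def transpose(self) -> "ConcordanceTable":
        return ConcordanceTable(self.a, self.c, self.b, self.d)

    def __add__(self, other: "ConcordanceTable") -> "ConcordanceTable":
        return ConcordanceTable(self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d)


def build_table(calls_a: Sequence[str], calls_b: Sequence[str]) -> ConcordanceTable:
    """Cross-tabulate paired MT/WT calls (same samples, same order)."""
    if len(calls_a) != len(calls_b):
        raise ConcordanceError(f"length mismatch: {len(calls_a)} vs {len(calls_b)}")
    counts = {"aa": 0, "ab": 0, "ba": 0, "bb": 0}
    for x, y in zip(calls_a, calls_b):
        if x not in (MT, WT) or y not in (MT, WT):
            raise ConcordanceError(f"calls must be 'MT' or 'WT', got ({x!r}, {y!r})")
        key = ("a" if x == MT else "b") + ("a" if y == MT else "b")
        counts[key] += 1
    return ConcordanceTable(counts["aa"], counts["ab"], counts["ba"], counts["bb"])


def cohen_kappa(table: ConcordanceTable) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    p_o is observed agreement; p_e the agreement expected from the marginal
    call frequencies.  Undefined (raises) when both methods call everything
    identically one-sided, since p_e = 1.
    """
    n = table.n
    if n == 0:
        raise ConcordanceError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e == 1.0:
        raise ConcordanceError("degenerate marginals: expected agreement is 1, kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_variants(tables: Mapping[str, ConcordanceTable]) -> dict[str, float]:
    """Per-table, pooled-count and mean-of-table kappa for a family of tables.

    Reported side by side because a single kappa spanning several strata can be
    pooled in more than one defensible way; none of these variants is claimed
    to match any externally reported value.
    """
    out = {f"kappa[{name}]": cohen_kappa(t) for name, t in tables.items()}
    pooled = None
    for t in tables.values():
        pooled = t if pooled is None else pooled + t
    out["kappa[pooled]"] = cohen_kappa(pooled)
    per = [v for k, v in out.items() if k.startswith("kappa[") and k != "kappa[pooled]"]
    out["kappa[mean_of_tables]"] = sum(per) / len(per)
    return out


def discordance_counts(tables: Iterable[ConcordanceTable]) -> dict[str, int]:
    """Tally discordant calls across tables oriented with the chip caller as rows.

    amds_only_mutants: called mutant by the chip but wild-type by sequencing;
    ds_only_mutants: the reverse; ds_mutant_total: all sequencing mutants.
    """
    tables = list(tables)
    return {
        "amds_only_mutants": sum(t.b for t in tables),
        "ds_only_mutants": sum(t.c for t in tables),
        "ds_mutant_total": sum(t.a + t.c for t in tables),
    }


def first_attempt_call_rate(n_total: int, n_failed: int) -> float:
    """Genotyping call rate in percent: successful / attempted * 100."""
    if n_total <= 0 or not (0 <= n_failed <= n_total):
        raise ConcordanceError(f"invalid counts: total={n_total}, failed={n_failed}")
    return (n_total - n_failed) / n_total * 100.0


@dataclass(frozen=True)
class CloneSet:
    """Clone-sequencing tally for one sample.

    Off-target alterations are scattered polymerase misreads; target-mutant
    clones carry the specific hotspot change under investigation.
    """

    sample_id: str
    insert_length: int
    n_clones_sequenced: int
    n_target_mutant_clones: int
    n_off_target_alterations: int

    def __post_init__(self) -> None:
        if self.insert_length <= 0:
            raise ConcordanceError("insert_length must be positive")
        if self.n_clones_sequenced <= 0:
            raise ConcordanceError("need at least one sequenced clone")
        if not (0 <= self.n_target_mutant_clones <= self.n_clones_sequenced):
            raise ConcordanceError("target-mutant clones exceed clones sequenced")
        if self.n_off_target_alterations < 0:
            raise ConcordanceError("alteration count must be non-negative")


def error_rate(clones: CloneSet) -> float:
    """Polymerase error rate in percent.

    ER = alterations / (insert length x clones sequenced) x 100 — misreads per
    sequenced base, expressed as a percentage.
    """
    return clones.n_off_target_alterations / (clones.insert_length * clones.n_clones_sequenced) * 100.0


def mutation_vs_error_test(
    clones: CloneSet | Sequence[CloneSet], er_percent: float
) -> float:
    """One-sided exact binomial test of mutant clones against polymerase error.

    Null: each clone independently shows the target base changed with
    probability p0 = ER/100 (the per-base error rate at that position).  The
    p-value is P[X >= k] for X ~ Binomial(n clones, p0).  A list of clone sets
    is pooled by summing k and n.
    """
    if not (0 < er_percent < 100):
        raise ConcordanceError(f"background ER must be in (0, 100) percent, got {er_percent}")
    sets = [clones] if isinstance(clones, CloneSet) else list(clones)
    k = sum(c.n_target_mutant_clones for c in sets)
    n = sum(c.n_clones_sequenced for c in sets)
    p0 = er_percent / 100.0
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass
class CohortReport:
    """Patient-level cohort summary."""

    n_patients: int
    gene_frequencies: pd.DataFrame  # gene, n_mutant_patients, frequency
    co_mutations: pd.DataFrame  # genes (sorted '+'-joined), mutations, n_patients
    paired_conflicts: list[str] = field(default_factory=list)


def summarize_cohort(
    genotypes: Sequence[SampleGenotype], patient_map: Mapping[str, str]
) -> CohortReport:
    """Aggregate sample genotypes to patients.

    Patients with several samples (e.g. frozen and FFPE slices of one tissue)
    are counted once; discrepant mutation sets between a patient's samples are
    flagged and resolved by union, the permissive choice given that the less
    sensitive preparation is expected to miss low-fraction mutations.
    """
    missing = [g.sample_id for g in genotypes if g.sample_id not in patient_map]
    if missing:
        raise ConcordanceError(f"patient_map missing samples: {missing}")
    per_patient: dict[str, list[frozenset[MutationTarget]]] = {}
    for g in genotypes:
        per_patient.setdefault(patient_map[g.sample_id], []).append(g.detected_mutations)

    conflicts = []
    patient_mutations: dict[str, frozenset[MutationTarget]] = {}
    for patient, sets in per_patient.items():
        if len({s for s in sets}) > 1:
            conflicts.append(
                f"patient {patient}: samples disagree "
                f"({[sorted(map(str, s)) for s in sets]}); union taken"
            )
        patient_mutations[patient] = frozenset().union(*sets)

    n_patients = len(patient_mutations)
    gene_rows = []
    for gene in PANEL_GENES:
        n_mut = sum(1 for s in patient_mutations.values() if any(m.gene == gene for m in s))
        gene_rows.append(
            {"gene": gene, "n_mutant_patients": n_mut,
             "frequency": n_mut / n_patients if n_patients else 0.0}
        )
    combo_rows: dict[tuple[str, str], int] = {}
    for s in patient_mutations.values():
        genes = sorted({m.gene for m in s})
        if len(genes) < 2:
            continue
        muts = "+".join(sorted(str(m) for m in s))
        key = ("+".join(genes), muts)
        combo_rows[key] = combo_rows.get(key, 0) + 1
    co_mut = pd.DataFrame(
        [{"genes": g, "mutations": m, "n_patients": c} for (g, m), c in sorted(combo_rows.items())],
        columns=["genes", "mutations", "n_patients"],
    )
    return CohortReport(
        n_patients=n_patients,
        gene_frequencies=pd.DataFrame(gene_rows),
        co_mutations=co_mut,
        paired_conflicts=conflicts,
    )
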