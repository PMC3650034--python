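"""Published counts from the clinical validation study of the chip caller.

The instrument was validated against direct Sanger sequencing (DS) on 89
frozen and 70 FFPE colorectal-cancer tissue sections (153 patients; six
patients contributed a paired frozen + FFPE slice), with a separate 41-sample
fully-automated run comparing the on-board DNA-purification cartridge against
a bench extraction kit.  This module transcribes the printed count data — the
per-gene 2x2 agreement tables, first-attempt call-rate counts, the
multiple-mutation sample list and the 41-sample run margins — so the
statistics modules can recompute the study's arithmetic from its inputs.

Only the published margins and tables are factual; where per-sample detail was
not printed (the mutation identity of each of the 41 fully-automated samples),
the reconstruction helpers generate a synthetic assignment consistent with the
printed margins and say so in their docstrings.
"""

from __future__ import annotations

from .assay_model import MutationTarget, PANEL
from .concordance import CloneSet, ConcordanceTable
from .genotyper import OverallStatus, SampleGenotype

#: Per-gene 2x2 tables, chip caller as rows / DS as columns, frozen sections.
FROZEN_TABLES: dict[str, ConcordanceTable] = {
    "KRAS": ConcordanceTable(31, 1, 0, 57),
    "BRAF": ConcordanceTable(2, 1, 0, 86),
    "PIK3CA": ConcordanceTable(8, 6, 0, 75),
}

#: Per-gene 2x2 tables for FFPE sections.  (The PIK3CA table's printed TOTAL
#: row is internally inconsistent; the cell counts used here reconcile with the
#: study-wide discordance and mutant totals.)
FFPE_TABLES: dict[str, ConcordanceTable] = {
    "KRAS": ConcordanceTable(21, 3, 0, 45),
    "BRAF": ConcordanceTable(1, 0, 0, 62),
    "PIK3CA": ConcordanceTable(5, 3, 0, 61),
}

#: DS first-attempt genotyping attempts and failures per sample set.
DS_CALL_ATTEMPTS = {"frozen": (89, 0), "ffpe": (70, 18)}

#: Samples with coexisting mutations across genes: (sample_id, preservation,
#: list of (gene, protein_change)).  One sample carried three mutations, with
#: E542K and E545K shown by cloning to lie on different alleles.
MULTI_MUTATION_SAMPLES: list[tuple[str, str, list[tuple[str, str]]]] = [
    ("60682", "frozen", [("KRAS", "G12D"), ("PIK3CA", "E545K")]),
    ("63439", "frozen", [("KRAS", "G12V"), ("PIK3CA", "E545K")]),
    ("41949", "frozen", [("KRAS", "G13D"), ("PIK3CA", "E545K")]),
    ("41950", "frozen", [("KRAS", "G13D"), ("PIK3CA", "E542K"), ("PIK3CA", "E545K")]),
    ("7053316", "ffpe", [("KRAS", "G12D"), ("PIK3CA", "E545K")]),
    ("60681", "ffpe", [("KRAS", "G12D"), ("PIK3CA", "E545K")]),
]

#: Fully-automated 41-sample run: cartridge extraction vs bench kit, overall
#: mutant/wild-type agreement (rows = chip caller on cartridge DNA).
AUTOMATED_RUN_TABLE = ConcordanceTable(22, 0, 0, 19)
AUTOMATED_RUN_N = 41
AUTOMATED_RUN_GENE_MUTANTS = {"KRAS": 14, "PIK3CA": 8}

#: Sequenced insert lengths (bp) for the cloning analysis, per amplicon.
CLONE_INSERT_LENGTHS = {"KRAS": 214, "BRAF": 228, "PIK3CA_ex9": 269, "PIK3CA_ex20": 273}

#: Observed polymerase error-rate ranges (percent per base) by enzyme class.
POLYMERASE_ER_RANGES = {"GoTaq": (0.16, 0.29), "PrimeSTAR_GXL": (0.03, 0.06)}


def genotype_from_mutations(
    sample_id: str, mutations: list[tuple[str, str]]
) -> SampleGenotype:
    """A call-free :class:`SampleGenotype` carrying a known mutation set."""
    detected = frozenset(MutationTarget(g, p) for g, p in mutations)
    overall = OverallStatus.MUTANT if detected else OverallStatus.WILD_TYPE
    return SampleGenotype(sample_id, (), detected, overall)


def multi_mutation_genotypes() -> list[SampleGenotype]:
    """The published multiple-mutation samples as genotypes (one per sample)."""
    return [
        genotype_from_mutations(sid, muts) for sid, _, muts in MULTI_MUTATION_SAMPLES
    ]


def automated_run_genotypes() -> list[SampleGenotype]:
    """Synthetic per-sample reconstruction of the 41-sample fully-automated run.

    Only the margins were published: 41 samples, 14 KRAS mutants, 8 PIK3CA
    mutants, 19 wild type, perfect agreement with the bench-extraction
    reference.  The specific mutation assigned to each sample is synthetic
    (cycled through the gene's panel); counts are exact.
    """
    genotypes = []
    idx = 0
    for gene, n in AUTOMATED_RUN_GENE_MUTANTS.items():
        panel = PANEL[gene]
        for i in range(n):
            genotypes.append(
                genotype_from_mutations(f"AUTO{idx:03d}", [(gene, panel[i % len(panel)])])
            )
            idx += 1
    while idx < AUTOMATED_RUN_N:
        genotypes.append(genotype_from_mutations(f"AUTO{idx:03d}", []))
        idx += 1
    return genotypes


def automated_run_paired_calls() -> tuple[list[str], list[str]]:
    """Paired MT/WT calls (cartridge vs bench reference) for the 41-sample run."""
    calls = [
        "MT" if g.overall is OverallStatus.MUTANT else "WT" for g in automated_run_genotypes()
    ]
    return calls, list(calls)
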