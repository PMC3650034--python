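"""First-principles-lite simulator of the InvaderPlus reaction.

No public dataset of instrument traces exists, so titration experiments are
reproduced from a generative model with three stages:

1. **Template sampling.**  Plasmid copies per well follow from mass and length
   (650 g/mol per bp, Avogadro); the mutant subset of the input copies is drawn
   binomially at the nominal mutant fraction.  Carrier human genomic DNA
   contributes additional *wild-type* target copies (~303 per ng at 3.3 pg per
   haploid genome).
2. **PCR.**  Logistic amplification with a shared amplicon plateau: both allele
   pools grow at the per-cycle efficiency scaled by (1 - total/cap), so allele
   fractions are essentially preserved and the plateau divides between alleles
   by input fraction.  Below 50 copies a pool duplicates binomially (seeded);
   above, the deterministic expectation is used.
3. **Invasive-cleavage readout.**  Each amplicon pool drives a saturating
   exponential fluorescence rise in its matched channel, ``gain * A * (1 -
   exp(-k_match t))``, plus a small leak at ``k_mismatch`` into the opposite
   channel (Cleavase essentially cannot cut a one-base-mismatched probe; the
   leak is kept small-but-nonzero for realism).  A linear background drift,
   a constant raw-baseline offset and i.i.d. Gaussian noise complete the trace,
   sampled at 1 s over the detection window.

A Sanger-sequencing comparator models the direct-sequencing limit of
detection: the mutant secondary peak height ratio equals the mutant fraction
plus electropherogram noise, and is only called when it reaches 25% of the
primary peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_model import (
    DETECTION_WINDOW_S,
    FluorescenceTrace,
    MutationTarget,
    ThresholdSet,
)
from .calibration import CalibrationSet, estimate_fnt, estimate_rpt
from .genotyper import CallStatus, call_channel, compute_sr

AVOGADRO = 6.02214076e23
#: Average molar mass of one double-stranded base pair, g/mol.
BP_MASS_G_PER_MOL = 650.0
#: Mass of one haploid human genome, fg (3.3 pg); one target copy per genome.
HUMAN_GENOME_FG = 3.3e3
#: Pool size below which PCR duplication is simulated stochastically.
STOCHASTIC_COPY_LIMIT = 50


def copies_from_mass(mass_fg: float, length_bp: float) -> int:
    """Double-stranded DNA copies in ``mass_fg`` femtograms of a ``length_bp`` molecule.

    1 fg of the 4.2 kb assay plasmid works out to ~221 copies.
    """
    if length_bp <= 0:
        raise ValueError(f"length must be positive, got {length_bp}")
    if mass_fg < 0:
        raise ValueError(f"mass must be non-negative, got {mass_fg}")
    grams = mass_fg * 1e-15
    return round(grams / (length_bp * BP_MASS_G_PER_MOL / AVOGADRO))


def simulate_pcr(
    copies0: float,
    cycles: int,
    efficiency: float,
    cap: float,
    rng: np.random.Generator | None = None,
) -> float:
    """Logistic PCR: per cycle n grows by ``efficiency * n * (1 - n/cap)``.

    Far from the plateau this is exponential with per-cycle factor
    (1 + efficiency); the pool saturates at ``cap``.  With an ``rng`` and fewer
    than 50 copies, the number of duplicated molecules per cycle is binomial —
    the dominant stochasticity at limiting dilution.
    """
    if not (0 < efficiency <= 1):
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    n = float(max(copies0, 0))
    for _ in range(cycles):
        if n <= 0:
            return 0.0
        p = efficiency * max(0.0, 1.0 - n / cap)
        if rng is not None and n < STOCHASTIC_COPY_LIMIT:
            n += rng.binomial(int(round(n)), p)
        else:
            n += n * p
        n = min(n, cap)
    return n


def _amplify_pools(
    n_mt: float,
    n_wt: float,
    cycles: int,
    efficiency: float,
    cap: float,
    rng: np.random.Generator | None,
) -> tuple[float, float]:
    """Co-amplify two allele pools competing for one amplicon plateau."""
    mt, wt = float(max(n_mt, 0)), float(max(n_wt, 0))
    for _ in range(cycles):
        total = mt + wt
        if total <= 0:
            break
        p = efficiency * max(0.0, 1.0 - total / cap)
        new_mt = rng.binomial(int(round(mt)), p) if (rng is not None and 0 < mt < STOCHASTIC_COPY_LIMIT) else mt * p
        new_wt = rng.binomial(int(round(wt)), p) if (rng is not None and 0 < wt < STOCHASTIC_COPY_LIMIT) else wt * p
        mt += new_mt
        wt += new_wt
        if mt + wt > cap:
            scale = cap / (mt + wt)
            mt *= scale
            wt *= scale
    return mt, wt


@dataclass(frozen=True)
class KineticsScenario:
    """Parameterization of one simulated well.

    Rates are per second; masses in femtograms (plasmid) and nanograms
    (carrier genomic DNA); fluorescence in arbitrary units.
    """

    target: MutationTarget | None = None
    mutant_fraction: float = 0.05
    template_mass_fg: float = 10.0
    template_length_bp: float = 4200.0
    carrier_genomic_mass_ng: float = 0.0
    pcr_cycles: int = 35
    pcr_efficiency: float = 0.9
    amplicon_cap: float = 1e12
    k_match: float = 0.02
    k_mismatch: float = 1e-5
    signal_gain: float = 5e-9
    drift_rate: float = 0.05
    noise_sd: float = 2.0
    baseline_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutant_fraction <= 1):
            raise ValueError(f"mutant_fraction must be in [0, 1], got {self.mutant_fraction}")
        if self.k_mismatch >= self.k_match:
            raise ValueError("k_mismatch must be smaller than k_match")
        for name in ("k_match", "k_mismatch", "drift_rate", "noise_sd", "signal_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_trace(
    scenario: KineticsScenario,
    window_s: float = DETECTION_WINDOW_S,
    well_id: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[FluorescenceTrace, FluorescenceTrace]:
    """Simulate one well: (mutant-channel trace, wild-type-channel trace).

    The mutant allele is read on F1 and the wild type on F2; traces are raw
    (baseline offset included, not baseline-corrected).  Bit-reproducible for a
    fixed scenario seed when no external ``rng`` is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    total = copies_from_mass(scenario.template_mass_fg, scenario.template_length_bp)
    if total > 0 and 0 < scenario.mutant_fraction < 1:
        n_mt = int(rng.binomial(total, scenario.mutant_fraction))
    else:
        n_mt = int(round(total * scenario.mutant_fraction))
    n_wt = total - n_mt
    n_wt += round(scenario.carrier_genomic_mass_ng * 1e6 / HUMAN_GENOME_FG)

    a_mt, a_wt = _amplify_pools(
        n_mt, n_wt, scenario.pcr_cycles, scenario.pcr_efficiency, scenario.amplicon_cap, rng
    )

    t = np.arange(0.0, window_s + 1.0)
    sat_match = 1.0 - np.exp(-scenario.k_match * t)
    sat_leak = 1.0 - np.exp(-scenario.k_mismatch * t)
    g = scenario.signal_gain
    common = scenario.drift_rate * t + scenario.baseline_level
    f_mt = g * a_mt * sat_match + g * a_wt * sat_leak + common
    f_wt = g * a_wt * sat_match + g * a_mt * sat_leak + common
    if scenario.noise_sd > 0:
        f_mt = f_mt + rng.normal(0.0, scenario.noise_sd, size=t.shape)
        f_wt = f_wt + rng.normal(0.0, scenario.noise_sd, size=t.shape)
    return (
        FluorescenceTrace(well_id, "F1", t, f_mt),
        FluorescenceTrace(well_id, "F2", t, f_wt),
    )


def calibrate_thresholds(
    scenario_template: KineticsScenario,
    replicates: int = 8,
    fnt_k: float = 3.0,
    rpt_method: str = "geometric",
    seed: int = 0,
) -> ThresholdSet:
    """Derive a ThresholdSet for the scenario's target from simulated control runs.

    Simulates no-template wells (FNT from mean + k*sd of F(EP)), wild-type-only
    wells and 5%-mutant wells (RPT from the SR separation), mirroring how the
    instrument's thresholds are set from 5% mutant / 95% wild-type plasmid
    mixtures.
    """
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3 * replicates)]
    probe = ThresholdSet(FNT=1.0, RPT=1.0)  # carries EP/JP only
    from .assay_model import baseline_correct

    cal = CalibrationSet(target=scenario_template.target)
    for i in range(replicates):
        ntc = replace(scenario_template, template_mass_fg=0.0, carrier_genomic_mass_ng=0.0)
        tr, _ = simulate_trace(ntc, rng=rngs[i])
        cal.fep_no_template.append(
            float(np.interp(probe.EP, tr.times, (baseline_correct(tr)).values))
        )
    for i in range(replicates):
        neg = replace(scenario_template, mutant_fraction=0.0)
        tr, _ = simulate_trace(neg, rng=rngs[replicates + i])
        cal.sr_negative.append(compute_sr(baseline_correct(tr), probe))
    for i in range(replicates):
        low = replace(scenario_template, mutant_fraction=0.05)
        tr, _ = simulate_trace(low, rng=rngs[2 * replicates + i])
        cal.sr_low_mutant.append(compute_sr(baseline_correct(tr), probe))
    fnt = estimate_fnt(cal.fep_no_template, k=fnt_k)
    rpt = estimate_rpt(cal, method=rpt_method, min_replicates=3)
    return ThresholdSet(FNT=fnt, RPT=rpt, EP=probe.EP, JP=probe.JP)


@dataclass
class TitrationReport:
    """Per-condition call rates plus the full per-replicate SR table."""

    summary: pd.DataFrame  # columns: mutant_fraction, mass_fg, replicates, call_rate
    replicates: pd.DataFrame  # columns: mutant_fraction, mass_fg, replicate, f_ep, sr, positive
    rate_criterion: float = 0.95

    def detection_limit(self, mass_fg: float) -> float | None:
        """Smallest mutant fraction called positive in >= 95% of replicates.

        None when no tested fraction reaches the criterion at that mass.
        """
        sub = self.summary[self.summary["mass_fg"] == mass_fg]
        ok = sub[(sub["call_rate"] >= self.rate_criterion) & (sub["mutant_fraction"] > 0)]
        return None if ok.empty else float(ok["mutant_fraction"].min())


def run_titration(
    fractions: Sequence[float],
    masses: Sequence[float],
    replicates: int,
    scenario_template: KineticsScenario,
    thresholds: ThresholdSet,
    seed: int = 0,
) -> TitrationReport:
    """Mutant-fraction x template-mass titration through the full caller.

    Each replicate simulates one well, baseline-corrects the mutant channel and
    applies the two-stage FNT/RPT decision.  SR is recorded as NaN when the
    replicate fell below FNT (SR undefined).
    """
    from .assay_model import baseline_correct

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(len(fractions) * len(masses) * replicates))
    rows = []
    for f in fractions:
        for m in masses:
            scen = replace(scenario_template, mutant_fraction=f, template_mass_fg=m)
            for r in range(replicates):
                rng = np.random.default_rng(next(child))
                mt_trace, _ = simulate_trace(scen, rng=rng)
                call = call_channel(baseline_correct(mt_trace), thresholds)
                rows.append(
                    {
                        "mutant_fraction": f,
                        "mass_fg": m,
                        "replicate": r,
                        "f_ep": call.f_ep,
                        "sr": np.nan if call.sr is None else call.sr,
                        "positive": call.status is CallStatus.POSITIVE,
                    }
                )
    rep = pd.DataFrame(rows)
    summary = (
        rep.groupby(["mutant_fraction", "mass_fg"], as_index=False)
        .agg(replicates=("positive", "size"), call_rate=("positive", "mean"))
    )
    return TitrationReport(summary=summary, replicates=rep)


#: Minor-peak fraction below which a Sanger electropherogram cannot distinguish
#: the mutant peak from background.
DS_LOD = 0.25


def simulate_ds_readout(
    mutant_fraction: float,
    noise_sd: float = 0.02,
    lod: float = DS_LOD,
    rng: np.random.Generator | None = None,
) -> tuple[bool, float]:
    """Direct-sequencing comparator: (detected, secondary-peak height ratio).

    The mutant secondary peak scales with the mutant fraction; detection is
    boundary-inclusive at the limit of detection (default 25%).
    """
    if not (0 <= mutant_fraction <= 1):
        raise ValueError(f"mutant_fraction must be in [0, 1], got {mutant_fraction}")
    ratio = float(mutant_fraction)
    if noise_sd > 0 and rng is not None:
        ratio += float(rng.normal(0.0, noise_sd))
    return ratio >= lod, ratio


def ds_detection_limit(
    fractions: Sequence[float],
    replicates: int = 100,
    noise_sd: float = 0.02,
    lod: float = DS_LOD,
    rate_criterion: float = 0.95,
    seed: int = 0,
) -> float | None:
    """Smallest fraction the Sanger comparator detects in >= 95% of replicates."""
    rng = np.random.default_rng(seed)
    best = None
    for f in sorted(f for f in fractions if f > 0):
        hits = sum(simulate_ds_readout(f, noise_sd, lod, rng)[0] for _ in range(replicates))
        if hits / replicates >= rate_criterion:
            best = f
            break
    return best
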