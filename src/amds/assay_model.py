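"""Domain types for the automated mutation-detection chip.

The instrument runs an InvaderPlus reaction (PCR followed by an invasive-cleavage
FRET readout) in up to 23 wells of a disposable DNA chip.  Each test well
interrogates one hotspot mutation of the colorectal-cancer panel; the two optical
channels report the two FRET-cassette dyes (F1 = FAM, 520/490 nm; F2 = Redmond
Red, 595/580 nm), one per allele.  Fluorescence is read once per second during a
10-minute isothermal detection step at 61 degC; all times in this package are
seconds from the start of that step.

This module holds the shared value types (traces, targets, wells, threshold
sets) and the trace primitives (baseline correction, interpolation) that the
genotyper, the calibration routines and the simulator all build on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

#: Length of the isothermal signal-detection window, in seconds.
DETECTION_WINDOW_S = 600.0

#: Number of reaction wells on one chip.
MAX_WELLS = 23

CHANNELS = ("F1", "F2")

#: Dye/wavelength annotation per optical channel (emission/excitation, nm).
CHANNEL_DYES = {"F1": ("FAM", 520, 490), "F2": ("RED", 595, 580)}

#: The 13-mutation hotspot panel, by gene.
PANEL: dict[str, tuple[str, ...]] = {
    "KRAS": ("G12A", "G12C", "G12D", "G12R", "G12S", "G12V", "G13D"),
    "BRAF": ("V600E",),
    "PIK3CA": ("E542K", "E545K", "E545G", "H1047L", "H1047R"),
}

PANEL_GENES = tuple(PANEL)

#: Default exon/domain annotation per gene (PIK3CA split by codon region).
_EXON_DOMAINS = {
    "KRAS": "exon 2",
    "BRAF": "exon 15",
    "PIK3CA-helical": "exon 9 helical domain",
    "PIK3CA-kinase": "exon 20 kinase domain",
}


class AssayModelError(ValueError):
    """Invalid domain object or layout."""


def _default_exon_domain(gene: str, protein_change: str) -> str:
    if gene == "PIK3CA":
        key = "PIK3CA-kinase" if protein_change.startswith("H1047") else "PIK3CA-helical"
        return _EXON_DOMAINS[key]
    return _EXON_DOMAINS[gene]


@dataclass(frozen=True, order=True)
class MutationTarget:
    """One hotspot mutation of the panel, identified by gene and protein change."""

    gene: str
    protein_change: str
    exon_domain: str = ""

    def __post_init__(self) -> None:
        if self.gene not in PANEL:
            raise AssayModelError(f"unknown gene {self.gene!r}; panel genes are {PANEL_GENES}")
        if self.protein_change not in PANEL[self.gene]:
            raise AssayModelError(
                f"unknown mutation {self.gene} {self.protein_change!r}; "
                f"panel mutations for {self.gene} are {PANEL[self.gene]}"
            )
        if not self.exon_domain:
            object.__setattr__(
                self, "exon_domain", _default_exon_domain(self.gene, self.protein_change)
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gene} {self.protein_change}"


def panel_targets() -> list[MutationTarget]:
    """All 13 panel mutations as :class:`MutationTarget`, in panel order."""
    return [MutationTarget(g, p) for g in PANEL for p in PANEL[g]]


@dataclass(frozen=True)
class FluorescenceTrace:
    """Time-ordered fluorescence readings for one well-channel.

    ``times`` are seconds from the start of the detection step, strictly
    increasing; ``values`` are arbitrary fluorescence units.  A trace is either
    raw or baseline-corrected (first reading subtracted); the genotyper only
    accepts corrected traces.
    """

    well_id: int
    channel: str
    times: np.ndarray
    values: np.ndarray
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.channel not in CHANNELS:
            raise AssayModelError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise AssayModelError("times and values must be 1-D arrays of equal length")
        if len(times) < 2:
            raise AssayModelError("a trace needs at least 2 readings")
        if not np.all(np.diff(times) > 0):
            # deliberately rejected rather than sorted: out-of-order timestamps
            # indicate an acquisition fault that silent sorting would mask
            raise AssayModelError("trace times must be strictly increasing")
        if times[0] < 0:
            raise AssayModelError("trace times must be non-negative")
        if self.baseline_corrected and values[0] != 0.0:
            raise AssayModelError("baseline-corrected trace must start at 0")

    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def baseline_correct(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Subtract the first reading from every value.

    Raises if the trace is already flagged as corrected — correcting twice is
    always a pipeline bug even though it would be numerically harmless on a
    zero-start trace.
    """
    if trace.baseline_corrected:
        raise AssayModelError(f"trace {trace.well_id}/{trace.channel} is already baseline-corrected")
    return replace(trace, values=trace.values - trace.values[0], baseline_corrected=True)


def signal_at(trace: FluorescenceTrace, t: float) -> float:
    """Fluorescence at time ``t``, linearly interpolated between readings.

    ``t`` must lie inside the sampled range; extrapolation is refused because
    the decision times (judging point, end point) must be covered by data.
    """
    t0, t1 = trace.span()
    if not (t0 <= t <= t1):
        raise AssayModelError(f"t={t} outside sampled range [{t0}, {t1}]")
    return float(np.interp(t, trace.times, trace.values))


@dataclass(frozen=True)
class ThresholdSet:
    """Decision parameters for one well-channel.

    EP (end point) and JP (judging point) are the two read-out times; FNT is the
    fluorescence negative threshold applied to F(EP); RPT is the positive ratio
    threshold applied to the signal ratio SR = F(JP)/F(EP).
    """

    FNT: float
    RPT: float
    EP: float = DETECTION_WINDOW_S
    JP: float = DETECTION_WINDOW_S / 2

    def __post_init__(self) -> None:
        if not (0 < self.JP < self.EP <= DETECTION_WINDOW_S):
            raise AssayModelError(
                f"need 0 < JP < EP <= {DETECTION_WINDOW_S}; got JP={self.JP}, EP={self.EP}"
            )
        if self.FNT <= 0:
            raise AssayModelError(f"FNT must be positive, got {self.FNT}")
        if self.RPT <= 0:
            raise AssayModelError(f"RPT must be positive, got {self.RPT}")


ROLES = ("test", "negative_control", "positive_control")


@dataclass(frozen=True)
class WellAssay:
    """Configuration of one chip well: target mutation, role, channel-to-allele map."""

    well_id: int
    role: str = "test"
    target: MutationTarget | None = None
    channel_allele_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.well_id <= MAX_WELLS):
            raise AssayModelError(f"well_id must be in 1..{MAX_WELLS}, got {self.well_id}")
        if self.role not in ROLES:
            raise AssayModelError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "test":
            if self.target is None:
                raise AssayModelError(f"test well {self.well_id} needs a target mutation")
            alleles = sorted(self.channel_allele_map.values())
            if (
                sorted(self.channel_allele_map) != sorted(CHANNELS)
                or alleles != ["mutant", "wild_type"]
            ):
                raise AssayModelError(
                    f"test well {self.well_id} must map exactly one channel to 'mutant' "
                    f"and one to 'wild_type', got {dict(self.channel_allele_map)!r}"
                )

    def channel_for(self, allele: str) -> str:
        """Optical channel reporting the given allele ('mutant' or 'wild_type')."""
        for channel, a in self.channel_allele_map.items():
            if a == allele:
                return channel
        raise AssayModelError(f"well {self.well_id}: no channel mapped to {allele!r}")


def _well_from_mapping(entry: Mapping) -> WellAssay:
    role = entry.get("role", "test")
    target = None
    if entry.get("gene") is not None:
        target = MutationTarget(entry["gene"], entry["protein_change"])
    channels = {str(k): str(v) for k, v in (entry.get("channels") or {}).items()}
    return WellAssay(
        well_id=int(entry["well_id"]), role=role, target=target, channel_allele_map=channels
    )


def load_chip_layout(source) -> list[WellAssay]:
    """Parse a chip-layout descriptor into validated :class:`WellAssay` records.

    ``source`` may be a YAML string, a path to a YAML file, or an already-parsed
    mapping of the same shape (top-level key ``wells``).  Validation enforces
    unique well ids, at most 23 wells, the 13-mutation panel vocabulary, and at
    most one test well per panel mutation.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = source
        try:
            import os

            if os.path.exists(str(source)):
                with open(source) as fh:
                    text = fh.read()
        except (TypeError, ValueError):
            pass
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "wells" not in doc:
        raise AssayModelError("layout descriptor must be a mapping with a 'wells' list")
    wells = [_well_from_mapping(entry) for entry in doc["wells"]]
    ids = [w.well_id for w in wells]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AssayModelError(f"duplicate well ids in layout: {dupes}")
    if len(wells) > MAX_WELLS:
        raise AssayModelError(f"layout has {len(wells)} wells; the chip holds {MAX_WELLS}")
    targets = [w.target for w in wells if w.role == "test"]
    if len(set(targets)) != len(targets):
        dupes = sorted({str(t) for t in targets if targets.count(t) > 1})
        raise AssayModelError(f"panel mutation assayed by more than one test well: {dupes}")
    return wells


def serialize_chip_layout(wells: Iterable[WellAssay]) -> str:
    """Inverse of :func:`load_chip_layout`; round-trips exactly."""
    entries = []
    for w in wells:
        entry: dict = {"well_id": w.well_id, "role": w.role}
        if w.target is not None:
            entry["gene"] = w.target.gene
            entry["protein_change"] = w.target.protein_change
        if w.channel_allele_map:
            entry["channels"] = dict(w.channel_allele_map)
        entries.append(entry)
    return yaml.safe_dump({"wells": entries}, sort_keys=False)
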