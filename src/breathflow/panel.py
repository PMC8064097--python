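"""Default ion-channel panel for a breath PTR-ToF-MS campaign.

Channels are named ``mz<value>`` after the instrument's peak label (the
measured centroid printed to two decimals), which is also the column name
used in trace tables and concentration matrices.  The panel mixes:

* the two primary-ion (reagent) channels used for normalization — the
  H3(18O)+ isotopologue at m/z 21.02 and the 18O water-cluster at 39.03;
* endogenous breath volatiles with known exercise response (acetone,
  isoprene, methanol, the short-chain fatty acids, ...);
* stable endogenous volatiles that do not respond to exercise
  (acetonitrile, dimethyl sulfide, ...), so that variable selection has
  genuine contrast;
* known product-ion fragments generated from their parent compounds at a
  fixed fragmentation fraction;
* exogenous channels (monoterpene, estragole) that are annotated but
  excluded from exercise models;
* unassigned low-signal channels that sit below the detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field


ROLES = ("primary", "endogenous", "exogenous", "fragment")

#: Ordered study timepoints: pre-walking baseline, three post-walking days
#: and one pre-walking morning sample on day 2.
TIMEPOINTS = ("Day0", "Day1", "Day2am", "Day2", "Day3")

#: Study groups: non-statin users, statin users without and with muscle
#: complaints.
GROUPS = ("St0", "St1", "St2")

#: Channel names of the short-chain fatty acid parent ions.
SCFA_IONS = ("mz61.03", "mz75.05", "mz89.06")


@dataclass(frozen=True)
class IonChannel:
    """One integrated peak of the ToF spectrum tracked at 1 Hz."""

    name: str                      # column label, "mz<printed centroid>"
    mz: float                      # printed centroid m/z
    formula: str | None = None     # protonated product-ion formula, if assigned
    role: str = "endogenous"       # one of ROLES
    compound: str | None = None    # tentative compound assignment
    parent: str | None = None      # for fragments: name of the parent channel
    fraction: float | None = None  # fragmentation fraction relative to parent

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.role == "fragment" and self.parent is None:
            raise ValueError(f"fragment channel {self.name} needs a parent")


def default_panel() -> list[IonChannel]:
    """The default campaign panel (primary ions, analytes, fragments)."""
    return [
        IonChannel("mz21.02", 21.02, "H3[18O]+", "primary", "hydronium (18O)"),
        IonChannel("mz39.03", 39.03, "H5O[18O]+", "primary",
                   "hydronium water cluster (18O)"),
        # endogenous, exercise responsive
        IonChannel("mz33.03", 33.03, "CH4OH+", "endogenous", "methanol"),
        IonChannel("mz45.03", 45.03, "C2H4OH+", "endogenous", "acetaldehyde"),
        IonChannel("mz47.05", 47.05, "C2H6OH+", "endogenous", "ethanol"),
        IonChannel("mz59.05", 59.05, "C3H6OH+", "endogenous", "acetone"),
        IonChannel("mz69.07", 69.07, "C5H8H+", "endogenous", "isoprene"),
        IonChannel("mz87.09", 87.09, "C5H10OH+", "endogenous",
                   "pentanone/3-methyl-2-butanone"),
        IonChannel("mz61.03", 61.03, "C2H4O2H+", "endogenous", "acetic acid"),
        IonChannel("mz75.05", 75.05, "C3H6O2H+", "endogenous", "propanoic acid"),
        IonChannel("mz89.06", 89.06, "C4H8O2H+", "endogenous", "butanoic acid"),
        # endogenous, stable under exercise
        IonChannel("mz31.02", 31.02, "CH2OH+", "endogenous", "formaldehyde"),
        IonChannel("mz42.03", 42.03, "C2H3NH+", "endogenous", "acetonitrile"),
        IonChannel("mz63.03", 63.03, "C2H6SH+", "endogenous", "dimethyl sulfide"),
        IonChannel("mz73.06", 73.06, "C4H8OH+", "endogenous", "butanone"),
        IonChannel("mz107.09", 107.09, "C8H10H+", "endogenous", "xylenes"),
        # product-ion fragments of endogenous parents
        IonChannel("mz43.02", 43.02, "C2H2OH+", "fragment", "acetic acid fragment",
                   parent="mz61.03", fraction=0.35),
        IonChannel("mz57.04", 57.04, "C3H4OH+", "fragment",
                   "propanoic acid fragment", parent="mz75.05", fraction=0.35),
        IonChannel("mz71.05", 71.05, "C4H6OH+", "fragment",
                   "butanoic acid fragment", parent="mz89.06", fraction=0.35),
        IonChannel("mz41.04", 41.04, "C3H4H+", "fragment", "isoprene fragment",
                   parent="mz69.07", fraction=0.30),
        # exogenous
        IonChannel("mz81.08", 81.08, "C6H8H+", "exogenous",
                   "monoterpene fragment"),
        IonChannel("mz137.13", 137.13, "C10H16H+", "exogenous", "monoterpene"),
        IonChannel("mz149.10", 149.10, "C10H12OH+", "exogenous",
                   "methyl chavicol (estragole)"),
        # unassigned channels at instrument-background level
        IonChannel("mz101.10", 101.10, None, "endogenous", None),
        IonChannel("mz115.11", 115.11, None, "endogenous", None),
    ]


def panel_by_name(panel: list[IonChannel]) -> dict[str, IonChannel]:
    return {ch.name: ch for ch in panel}


def primary_channels(panel: list[IonChannel]) -> tuple[str, str]:
    """Return (m/z 21.02 channel, m/z 39.03 channel) names."""
    prim = [ch.name for ch in panel if ch.role == "primary"]
    lo = [n for n in prim if "21.02" in n]
    hi = [n for n in prim if "39.03" in n]
    if len(lo) != 1 or len(hi) != 1:
        raise ValueError(
            "panel must contain exactly one primary-ion channel each for "
            "m/z 21.02 and m/z 39.03")
    return lo[0], hi[0]


def analyte_channels(panel: list[IonChannel]) -> list[str]:
    """All non-primary channel names, in panel order."""
    return [ch.name for ch in panel if ch.role != "primary"]
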