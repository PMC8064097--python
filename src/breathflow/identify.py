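"""Ion identification: accurate-mass formula assignment and correlation
clustering of related channels (fragments, hydrates).

Formula parsing accepts protonated product-ion formulas over C, H, O, N, S
with optional isotope markers in bracket notation (``H3[18O]+``).  Atomic
masses come from the NIST table shipped with :mod:`pyteomics`; the reported
ion m/z is the monoisotopic mass of the composition minus one electron mass
(charge +1).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .panel import IonChannel

logger = logging.getLogger(__name__)

#: CODATA electron mass in unified atomic mass units.
ELECTRON_MASS_U = 0.000548579909

_ALLOWED_ELEMENTS = {"C", "H", "O", "N", "S"}

_TOKEN = re.compile(
    r"\[(?P<iso>\d+)(?P<isoel>[A-Z][a-z]?)\]"   # [18O]
    r"|(?P<el>[A-Z][a-z]?)"                      # plain element
)


def parse_formula(formula: str) -> dict[tuple[str, int | None], int]:
    """Parse a protonated-ion formula into {(element, isotope): count}.

    A single trailing ``+`` (charge +1) is allowed and stripped.  Raises
    ``ValueError`` naming the offending token on anything unparseable.
    """
    body = formula.strip()
    if body.endswith("+"):
        body = body[:-1]
    if not body:
        raise ValueError(f"empty formula {formula!r}")
    comp: dict[tuple[str, int | None], int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN.match(body, pos)
        if m is None:
            raise ValueError(
                f"cannot parse formula {formula!r}: offending token "
                f"{body[pos:]!r}")
        if m.group("iso"):
            element, isotope = m.group("isoel"), int(m.group("iso"))
        else:
            element, isotope = m.group("el"), None
        if element not in _ALLOWED_ELEMENTS:
            raise ValueError(
                f"cannot parse formula {formula!r}: unknown element "
                f"{element!r}")
        pos = m.end()
        num = re.match(r"\d+", body[pos:])
        count = int(num.group()) if num else 1
        pos += num.end() if num else 0
        key = (element, isotope)
        comp[key] = comp.get(key, 0) + count
    return comp


def theoretical_mz(formula: str, charge: int = 1) -> float:
    """Monoisotopic m/z of a (singly) protonated product ion.

    Sum of atomic masses of the composition minus ``charge`` electron
    masses, divided by ``charge``.
    """
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    comp = parse_formula(formula)
    total = 0.0
    for (element, isotope), count in comp.items():
        table = _ptmass.nist_mass[element]
        key = isotope if isotope is not None else 0
        if key not in table:
            raise ValueError(f"no mass for isotope {isotope} of {element}")
        total += table[key][0] * count
    return (total - charge * ELECTRON_MASS_U) / charge


@dataclass
class FormulaMatch:
    formula: str
    compound: str | None
    theoretical: float
    ppm_error: float


def match_formula(measured_mz: float,
                  candidates: list[IonChannel] | pd.DataFrame,
                  tol_ppm: float = 20.0) -> list[FormulaMatch]:
    """Rank candidate formulas for a measured m/z by |ppm error|.

    ``candidates`` is either a list of :class:`IonChannel` or a frame with
    ``formula`` (and optionally ``compound``) columns.  Candidates without
    a formula are skipped.  An empty list means no match within tolerance.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if isinstance(candidates, pd.DataFrame):
        rows = [(r.get("formula"), r.get("compound"))
                for _, r in candidates.iterrows()]
    else:
        rows = [(ch.formula, ch.compound) for ch in candidates]
    out: list[FormulaMatch] = []
    for formula, compound in rows:
        if not formula:
            continue
        theo = theoretical_mz(formula)
        ppm = (measured_mz - theo) / theo * 1e6
        if abs(ppm) <= tol_ppm:
            out.append(FormulaMatch(formula, compound, theo, ppm))
    out.sort(key=lambda m: abs(m.ppm_error))
    return out


def correlate_ions(values: pd.DataFrame, r2_cut: float = 0.85,
                   log: bool = True) -> dict[str, int]:
    """Group related channels (fragments/clusters) by Pearson correlation.

    Two channels are linked when their squared Pearson correlation across
    samples is >= ``r2_cut``; clusters are the connected components of the
    resulting graph.  Correlation is computed on log values by default,
    matching the pipeline transform.  A constant channel has undefined
    correlation and becomes a singleton.

    Returns {channel name: cluster id}; cluster ids are assigned in order
    of each cluster's first channel after sorting names, so the labelling
    does not depend on column order.
    """
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate channels")
    cols = sorted(values.columns)
    x = values[cols].to_numpy(dtype=float)
    if log:
        if (x <= 0).any():
            raise ValueError("log correlation requires positive values")
        x = np.log(x)
    sd = x.std(axis=0)
    constant = sd == 0
    for name in np.asarray(cols)[constant]:
        logger.info("channel %s is constant; correlation undefined, kept "
                    "as a singleton cluster", name)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    adj = np.nan_to_num(r, nan=0.0) ** 2 >= r2_cut
    adj[constant, :] = False
    adj[:, constant] = False
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # relabel deterministically by first occurrence over sorted names
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for name, lab in zip(cols, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[name] = remap[lab]
    return out


def annotate_channels(panel: list[IonChannel], values: pd.DataFrame | None,
                      tol_ppm: float = 150.0,
                      r2_cut: float = 0.85) -> pd.DataFrame:
    """Build the annotation table: formula match, ppm error, cluster id.

    ``values`` (samples x channels, concentrations) drives the correlation
    clustering; when omitted every channel is its own cluster.  The mass
    tolerance default is generous because channel labels are printed to
    two decimals only.
    """
    if values is not None:
        clusters = correlate_ions(values, r2_cut=r2_cut)
    else:
        clusters = {ch.name: i for i, ch in enumerate(panel)}
    records = []
    for ch in panel:
        if ch.name not in clusters and values is not None:
            continue
        matches = match_formula(ch.mz, [ch], tol_ppm=tol_ppm) if ch.formula else []
        best = matches[0] if matches else None
        if ch.role == "exogenous":
            source = "exogenous"
        elif best is not None:
            source = "mass-match"
        else:
            source = "correlation"
        records.append({
            "ion": ch.name,
            "mz": ch.mz,
            "formula": ch.formula,
            "compound": ch.compound,
            "theoretical_mz": best.theoretical if best else np.nan,
            "ppm_error": best.ppm_error if best else np.nan,
            "cluster_id": clusters.get(ch.name, -1),
            "source": source,
        })
    return pd.DataFrame.from_records(records)
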