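"""Pollution and ecological-risk indices.

Per sample and element: the contamination factor CF = C/Bn, the Müller
geo-accumulation index Igeo = log2(C / (1.5 Bn)) and the Hakanson ecological
risk factor ER = Tr * CF.  Per sample: the Tomlinson pollution load index
PLI = (prod CF)^(1/n) and the potential ecological risk index PERI = sum ER.
Classification bands follow the Hakanson/Müller conventions; interval
boundaries are lower-closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ELEMENTS, LAND_USES, ReferenceTables, SoilDataset


def contamination_factor(c: float, background: float) -> float:
    """Enrichment of a concentration relative to geochemical background."""
    if background <= 0:
        raise ValueError("background must be positive")
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return c / background


def geo_accumulation_index(c: float, background: float) -> float:
    """Igeo = log2(C / (1.5 Bn)); the 1.5 buffers natural background
    fluctuation."""
    if c <= 0 or background <= 0:
        raise ValueError("Igeo requires positive concentration and background")
    return float(np.log2(c / (1.5 * background)))


def pollution_load_index(cfs) -> float:
    """Geometric mean of contamination factors."""
    cfs = np.asarray(list(cfs), float)
    if cfs.size == 0:
        raise ValueError("PLI requires at least one contamination factor")
    if (cfs <= 0).any():
        raise ValueError("PLI requires strictly positive contamination factors")
    return float(np.exp(np.mean(np.log(cfs))))


def ecological_risk(tr: float, cf: float) -> float:
    if tr < 0 or cf < 0:
        raise ValueError("tr and cf must be non-negative")
    return tr * cf


def potential_ecological_risk_index(ers) -> float:
    ers = np.asarray(list(ers), float)
    if ers.size and (ers < 0).any():
        raise ValueError("ER values must be non-negative")
    return float(ers.sum())


# ---------------------------------------------------------------------------
# classification

# (lower bound, label); intervals are lower-closed: value in [b_i, b_{i+1}).
_BANDS: dict[str, list[tuple[float, str]]] = {
    "CF": [
        (-np.inf, "low"),
        (1.0, "moderate"),
        (3.0, "considerable"),
        (6.0, "severe"),
    ],
    "ER": [
        (-np.inf, "low"),
        (40.0, "moderate"),
        (80.0, "considerable"),
        (160.0, "high"),
        (320.0, "very high"),
    ],
    "PERI": [
        (-np.inf, "low"),
        (150.0, "moderate"),
        (300.0, "considerable"),
        (600.0, "high"),
    ],
    "Igeo": [
        (-np.inf, "unpolluted"),
        (0.0, "unpolluted to moderately polluted"),
        (1.0, "moderately polluted"),
        (2.0, "moderately to heavily polluted"),
        (3.0, "heavily polluted"),
        (4.0, "heavily to extremely polluted"),
        (5.0, "extremely polluted"),
    ],
    "PLI": [
        (-np.inf, "unpolluted"),
        (1.0, "polluted"),
    ],
}

#: Operational severe-contamination screen reported alongside CF classes.
CF_SEVERE_FLAG_THRESHOLD = 5.0


def classify_index(value: float, index_kind: str) -> str:
    """Class label for a finite index value; unknown kinds are errors."""
    if index_kind not in _BANDS:
        raise ValueError(f"unknown index kind {index_kind!r}")
    if not np.isfinite(value):
        raise ValueError("index value must be finite")
    label = _BANDS[index_kind][0][1]
    for lower, name in _BANDS[index_kind]:
        if value >= lower:
            label = name
    # PLI's upper band is "polluted" strictly above 1
    if index_kind == "PLI":
        return "polluted" if value > 1.0 else "unpolluted"
    return label


@dataclass
class IndexTable:
    """Per-sample/per-element CF, Igeo and ER plus per-sample PLI and PERI.

    ``per_element`` is a long-format DataFrame (sample_id, land_use, element,
    CF, Igeo, ER and their class labels); ``per_sample`` holds PLI and PERI.
    ``cf_severe_rate`` reports, per land use and element, the percentage of
    samples with CF above the severe-contamination screen (CF > 5).
    """

    per_element: pd.DataFrame
    per_sample: pd.DataFrame
    cf_severe_rate: pd.DataFrame


def index_table(ds: SoilDataset, refs: ReferenceTables) -> IndexTable:
    """Compute every index for every sample of a dataset."""
    conc = ds.concentrations()
    bn = np.array([refs.background[el] for el in ELEMENTS])
    tr = np.array([refs.toxic_response.get(el, 0.0) for el in ELEMENTS])
    if (conc <= 0).any():
        raise ValueError(
            "zero concentrations present; apply an MDL substitution policy "
            "before computing Igeo/PLI"
        )
    cf = conc / bn
    igeo = np.log2(conc / (1.5 * bn))
    er = cf * tr
    pli = np.exp(np.mean(np.log(cf), axis=1))
    peri = er.sum(axis=1)

    rows = []
    for i in range(ds.n):
        for j, el in enumerate(ELEMENTS):
            rows.append({
                "sample_id": ds.df["sample_id"].iloc[i],
                "land_use": ds.df["land_use"].iloc[i],
                "element": el,
                "CF": cf[i, j],
                "CF_class": classify_index(cf[i, j], "CF"),
                "CF_severe": bool(cf[i, j] > CF_SEVERE_FLAG_THRESHOLD),
                "Igeo": igeo[i, j],
                "Igeo_class": classify_index(igeo[i, j], "Igeo"),
                "ER": er[i, j],
                "ER_class": classify_index(er[i, j], "ER"),
            })
    per_element = pd.DataFrame(rows)
    per_sample = pd.DataFrame({
        "sample_id": ds.df["sample_id"],
        "land_use": ds.df["land_use"],
        "PLI": pli,
        "PLI_class": [classify_index(v, "PLI") for v in pli],
        "PERI": peri,
        "PERI_class": [classify_index(v, "PERI") for v in peri],
    })
    severe = (
        per_element.assign(sev=per_element["CF_severe"].astype(float) * 100.0)
        .pivot_table(index="land_use", columns="element", values="sev",
                     aggfunc="mean")
        .reindex([lu for lu in LAND_USES if lu in set(ds.land_use)])
        .reindex(columns=list(ELEMENTS))
    )
    return IndexTable(per_element, per_sample, severe)
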