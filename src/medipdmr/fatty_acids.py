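"""Derived fatty-acid features: family totals and diagnostic ratios.

FA columns are named in the C<carbons>:<double bonds><family> convention
(e.g. ``C22:6ω3``). Saturation class follows the double-bond count
(0 saturated, 1 monounsaturated, >= 2 polyunsaturated) and the omega
family follows the suffix. Family totals (SFA, MUFA, PUFA, omega-3,
omega-6) and six ratios — ω3/ω6, PUFA/SFA, SFA/UFA, MUFA/SFA,
C18:2ω6/C20:4ω6 and C22:6ω3/C20:4ω6 — are appended per lipid fraction
(phospholipids and neutral lipids). The C22:6ω3/C20:4ω6 ratio tracks the
balance between anti- and pro-inflammatory FA derivatives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_FA_RE = re.compile(r"^C(\d+):(\d+)(?:[ωwn]-?(\d+))?$")

#: the FA panel detected in both adults and perinatal animals
CORE_FAS = ["C14:0", "C16:0", "C16:1ω7", "C18:0", "C18:1ω9", "C18:2ω6",
            "C18:3ω3", "C20:3ω6", "C20:4ω6", "C20:5ω3", "C22:4ω6",
            "C22:5ω3", "C22:6ω3"]

#: variables removed from the rank-PCA because of near-redundancy with
#: their counterpart in the other lipid fraction
RANK_PCA_DROPS = ["PL C18:1ω9", "NL C20:3ω6", "PL C22:4ω6", "NL C20:5ω3"]

FAMILY_TOTALS = ["SFA", "MUFA", "PUFA", "ω3", "ω6"]
RATIOS = ["ω3/ω6", "PUFA/SFA", "SFA/UFA", "MUFA/SFA",
          "C18:2ω6/C20:4ω6", "C22:6ω3/C20:4ω6"]


@dataclass(frozen=True)
class FAName:
    carbons: int
    double_bonds: int
    family: int | None  # omega number, None for saturated FAs

    @property
    def saturation(self) -> str:
        if self.double_bonds == 0:
            return "SFA"
        return "MUFA" if self.double_bonds == 1 else "PUFA"


def parse_fa_name(name: str) -> FAName:
    m = _FA_RE.match(name.strip())
    if not m:
        raise ValueError(f"unrecognised fatty-acid name: {name!r}")
    carbons, db, fam = int(m.group(1)), int(m.group(2)), m.group(3)
    if db > 0 and fam is None:
        raise ValueError(f"unsaturated FA without omega family: {name!r}")
    return FAName(carbons, db, int(fam) if fam else None)


def _safe_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    out = num / den.where(den > 0)
    return out.astype(float)


def fa_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Append family totals and ratios to a per-animal FA percentage table.

    ``raw`` has animals as rows and FA percentage columns for one lipid
    fraction. Unknown column names raise. Ratios with a zero or absent
    denominator are left missing.
    """
    parsed = {col: parse_fa_name(col) for col in raw.columns}
    if (raw < 0).any().any():
        bad = raw.columns[(raw < 0).any()][0]
        raise ValueError(f"negative percentage in column {bad!r}")
    out = raw.copy()
    classes = {"SFA": [], "MUFA": [], "PUFA": [], "ω3": [], "ω6": []}
    for col, fa in parsed.items():
        classes[fa.saturation].append(col)
        if fa.family in (3, 6):
            classes[f"ω{fa.family}"].append(col)
    for total, members in classes.items():
        out[total] = raw[members].sum(axis=1) if members else 0.0

    ufa = out["MUFA"] + out["PUFA"]
    out["ω3/ω6"] = _safe_ratio(out["ω3"], out["ω6"])
    out["PUFA/SFA"] = _safe_ratio(out["PUFA"], out["SFA"])
    out["SFA/UFA"] = _safe_ratio(out["SFA"], ufa)
    out["MUFA/SFA"] = _safe_ratio(out["MUFA"], out["SFA"])
    for num, den in (("C18:2ω6", "C20:4ω6"), ("C22:6ω3", "C20:4ω6")):
        label = f"{num}/{den}"
        if num in raw.columns and den in raw.columns:
            out[label] = _safe_ratio(raw[num], raw[den])
        else:
            out[label] = np.nan
    return out


def fa_variable_set(fractions: dict) -> pd.DataFrame:
    """Build the MFA ``FA`` variable set from per-fraction tables.

    ``fractions`` maps a fraction prefix (``PL``, ``NL``) to a raw FA
    percentage table; each is expanded by :func:`fa_features` and
    prefixed, e.g. ``PL C22:6ω3``. With the 13-FA core panel in both
    fractions this yields (13 + 5 + 6) * 2 = 48 variables.
    """
    parts = []
    for prefix, table in fractions.items():
        feats = fa_features(table)
        feats.columns = [f"{prefix} {c}" for c in feats.columns]
        parts.append(feats)
    return pd.concat(parts, axis=1)


def rank_pca_variables(fractions: dict, drop=RANK_PCA_DROPS) -> pd.DataFrame:
    """Per-fraction raw FA percentages minus the listed redundant columns.

    This is the 22-variable input of the rank-PCA (13 FAs x 2 fractions
    minus 4 removals).
    """
    parts = []
    for prefix, table in fractions.items():
        t = table.copy()
        t.columns = [f"{prefix} {c}" for c in t.columns]
        parts.append(t)
    merged = pd.concat(parts, axis=1)
    return merged.drop(columns=[c for c in drop if c in merged.columns])
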