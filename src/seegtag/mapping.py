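"""Thresholding, responsive-contact classification, and ROI summaries.

Significance of tracking at a tagged rate is decided by comparing the
Rayleigh-Z value at that frequency bin against a study-wide threshold.
The reference analysis used a literal threshold of z = 5.29 (described
as p = 0.001, two-tailed normal, Bonferroni-corrected over all contacts
and three conditions); that literal value is the default here. Two
derived modes are also provided:

* ``derived-normal`` -- the standard-normal two-tailed quantile at
  alpha / n_tests, i.e. the recipe as stated;
* ``derived-rayleigh`` -- inverts the Rayleigh-test p-value of
  z = n * R**2, whose null distribution is approximately Exp(1), *not*
  standard normal. Only this mode yields nominal false-positive
  calibration on null data, so it is what the calibration checks use.

Responding percentages are reported to 2 decimals study-wide and as
integers in the per-ROI table, matching the conventions of the summary
tables this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spectral import SpectralError, ZSpectrum, rayleigh_p, value_at_frequency

#: Tagged linguistic rates, Hz.
DEFAULT_TAGS = (1.0, 2.0, 4.0)

#: Literal significance threshold on the Rayleigh-Z scale.
LITERAL_Z = 5.29

#: (condition, tag Hz) "home" cells used for selectivity classification.
HOME_CELLS = {"f_syl": ("syllable", 4.0), "f_phr": ("phrase", 2.0),
              "f_sen": ("sentence", 1.0)}

SELECTIVITY_CLASSES = ("selective_higher_order", "non_selective",
                       "syllable_only", "non_responsive")


class MappingError(ValueError):
    """Raised on contract violations in response mapping."""


@dataclass(frozen=True)
class ThresholdSpec:
    """How the significance threshold is obtained.

    mode "literal" returns ``literal_z`` unchanged. The derived modes
    Bonferroni-correct ``alpha`` over ``n_tests`` (by convention
    n_contacts x 3 conditions) and invert either the two-tailed
    standard-normal quantile ("derived-normal") or the Rayleigh-test
    null distribution ("derived-rayleigh", requires ``n_trials``).
    """

    mode: str = "literal"
    literal_z: float = LITERAL_Z
    alpha: float = 0.001

    def __post_init__(self) -> None:
        if self.mode not in ("literal", "derived-normal", "derived-rayleigh"):
            raise MappingError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "literal" and self.literal_z <= 0:
            raise MappingError("literal_z must be positive")
        if not 0 < self.alpha < 1:
            raise MappingError("alpha must lie in (0, 1)")


def resolve_threshold(
    spec: ThresholdSpec, n_tests: int = 1, n_trials: int | None = None
) -> float:
    """Z threshold implied by a ThresholdSpec.

    ``n_tests`` is the Bonferroni family size (n_contacts x 3 by the
    study-wide convention; ignored in literal mode).
    """
    if spec.mode == "literal":
        return float(spec.literal_z)
    if n_tests < 1:
        raise MappingError("n_tests must be >= 1")
    alpha_corr = spec.alpha / n_tests
    if spec.mode == "derived-normal":
        return float(stats.norm.isf(alpha_corr / 2.0))
    if n_trials is None or n_trials < 2:
        raise MappingError("derived-rayleigh threshold requires n_trials >= 2")
    f = lambda z: rayleigh_p(z, n_trials) - alpha_corr
    hi = min(float(n_trials), max(2.0, -np.log(alpha_corr) + 5.0))
    return float(optimize.brentq(f, 1e-9, hi))


def classify_responsive(
    zspectra: list[ZSpectrum],
    threshold: float,
    tags: tuple[float, ...] = DEFAULT_TAGS,
    conditions: tuple[str, ...] = ("syllable", "phrase", "sentence"),
) -> pd.DataFrame:
    """Flag each (contact, condition, tag, spectrum kind) cell.

    A cell is significant when its tagged-bin z meets the threshold;
    exact ties count as significant (``>=`` rule). Every contact must
    have a spectrum for every condition present in ``conditions`` for
    each spectrum kind it appears with; a missing condition is an error
    naming the contact.
    """
    by_key: dict[tuple[str, str], dict[str, ZSpectrum]] = {}
    for zs in zspectra:
        by_key.setdefault((zs.contact_id, zs.kind), {})[zs.condition] = zs
    rows = []
    for (contact_id, kind), conds in sorted(by_key.items()):
        missing = set(conditions) - set(conds)
        if missing:
            raise MappingError(
                f"contact {contact_id} ({kind}) missing conditions {sorted(missing)}"
            )
        for cond in conditions:
            zs = conds[cond]
            for tag in tags:
                z = value_at_frequency(zs, tag)
                rows.append({
                    "contact_id": contact_id,
                    "condition": cond,
                    "tag_hz": tag,
                    "spectrum_kind": kind,
                    "z": round(z, 6),
                    "significant": bool(not np.isnan(z) and z >= threshold),
                })
    return pd.DataFrame(rows)


def responding_percentage(n_flagged: int, total_contacts: int) -> float:
    """Percent of contacts flagged, to 2 decimals (e.g. 502/1743 -> 28.80)."""
    if total_contacts < 1:
        raise MappingError("total_contacts must be >= 1")
    return round(100.0 * n_flagged / total_contacts, 2)


def percentage_table(
    flags: pd.DataFrame, total_contacts: int,
    spectrum_kind: str = "broadband",
) -> pd.DataFrame:
    """Study-wide responding percentage per condition x tag."""
    sub = flags[flags["spectrum_kind"] == spectrum_kind]
    rows = []
    for (cond, tag), grp in sub.groupby(["condition", "tag_hz"], sort=True):
        n = int(grp["significant"].sum())
        rows.append({
            "condition": cond, "tag_hz": tag, "n_responsive": n,
            "total_contacts": total_contacts,
            "percent": responding_percentage(n, total_contacts),
        })
    return pd.DataFrame(rows)


def roi_table(
    flags: pd.DataFrame,
    contacts: pd.DataFrame,
    rois: tuple[str, ...] = ("HG", "STG", "MTG", "ITG", "IFG"),
    spectrum_kind: str = "broadband",
) -> pd.DataFrame:
    """Responding percentage per (hemisphere, ROI, condition, tag).

    ``contacts`` needs columns contact_id / hemisphere / roi. Contacts
    with an ROI outside ``rois`` are pooled into an "other" bucket that
    is reported after the named ROIs. Percentages are rounded to
    integers; the denominator (ROI contact count) is included per row.
    ROIs with zero contacts are omitted rather than reported as 0/0.
    """
    meta = contacts.set_index("contact_id")
    sub = flags[flags["spectrum_kind"] == spectrum_kind].copy()
    unknown = set(sub["contact_id"]) - set(meta.index)
    if unknown:
        raise MappingError(f"flags reference contacts without metadata: "
                           f"{sorted(unknown)[:5]}")
    sub["hemisphere"] = sub["contact_id"].map(meta["hemisphere"])
    sub["roi"] = sub["contact_id"].map(meta["roi"]).where(
        sub["contact_id"].map(meta["roi"]).isin(rois), "other")
    rows = []
    for hemi in ("L", "R"):
        for roi in (*rois, "other"):
            cell = sub[(sub["hemisphere"] == hemi) & (sub["roi"] == roi)]
            denom = cell["contact_id"].nunique()
            if denom == 0:
                continue
            for (cond, tag), grp in cell.groupby(["condition", "tag_hz"], sort=True):
                n = int(grp["significant"].sum())
                rows.append({
                    "hemisphere": hemi, "roi": roi,
                    "n_contacts": denom,
                    "condition": cond, "tag_hz": tag,
                    "n_responsive": n,
                    "percent": int(round(100.0 * n / denom)),
                })
    return pd.DataFrame(rows)


def classify_selectivity(
    flags: pd.DataFrame, spectrum_kind: str = "broadband"
) -> pd.DataFrame:
    """Assign each contact a selectivity class from its home-cell flags.

    Home cells: 4 Hz in the syllable condition (f_syl), 2 Hz in the
    phrase condition (f_phr), 1 Hz in the sentence condition (f_sen).
    Classes (mutually exclusive, exhaustive):

    * ``selective_higher_order`` -- f_phr+ or f_sen+, and f_syl-
    * ``non_selective``          -- f_phr+ or f_sen+, and f_syl+
    * ``syllable_only``          -- f_syl+ only
    * ``non_responsive``         -- all home cells negative

    Contacts with an undefined home cell (NaN z) are excluded with a
    logged reason.
    """
    import logging

    sub = flags[flags["spectrum_kind"] == spectrum_kind]
    rows = []
    for contact_id, grp in sub.groupby("contact_id", sort=True):
        cell_flags = {}
        ok = True
        for name, (cond, tag) in HOME_CELLS.items():
            match = grp[(grp["condition"] == cond) & (grp["tag_hz"] == tag)]
            if len(match) != 1 or np.isnan(match["z"].iloc[0]):
                logging.getLogger(__name__).warning(
                    "contact %s: home cell %s undefined, excluded", contact_id, name
                )
                ok = False
                break
            cell_flags[name] = bool(match["significant"].iloc[0])
        if not ok:
            continue
        higher = cell_flags["f_phr"] or cell_flags["f_sen"]
        if higher and not cell_flags["f_syl"]:
            cls = "selective_higher_order"
        elif higher:
            cls = "non_selective"
        elif cell_flags["f_syl"]:
            cls = "syllable_only"
        else:
            cls = "non_responsive"
        rows.append({
            "contact_id": contact_id,
            "f_syl": cell_flags["f_syl"], "f_phr": cell_flags["f_phr"],
            "f_sen": cell_flags["f_sen"], "selectivity": cls,
        })
    return pd.DataFrame(
        rows, columns=["contact_id", "f_syl", "f_phr", "f_sen", "selectivity"]
    )


def truth_selectivity(truth) -> pd.DataFrame:
    """Ground-truth selectivity classes implied by ContactTruth records.

    Applies the same home-cell rule to the generative truth, for scoring
    recovered classifications on synthetic studies.
    """
    rows = []
    for t in truth:
        cells = {
            "f_syl": 4.0 in t.locked_tags.get("syllable", ()),
            "f_phr": 2.0 in t.locked_tags.get("phrase", ()),
            "f_sen": 1.0 in t.locked_tags.get("sentence", ()),
        }
        higher = cells["f_phr"] or cells["f_sen"]
        if higher and not cells["f_syl"]:
            cls = "selective_higher_order"
        elif higher:
            cls = "non_selective"
        elif cells["f_syl"]:
            cls = "syllable_only"
        else:
            cls = "non_responsive"
        rows.append({"contact_id": t.contact_id, "selectivity": cls, **cells})
    return pd.DataFrame(rows)
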