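"""Canonicalisation of names, postcodes and dates of birth.

Both sources are brought into a single comparable form before any
matching: names upper-cased with diacritics stripped and punctuation
removed, postcodes normalised to ``OUTWARD INWARD`` and validated against
the look-up table (invalid codes are flagged, never dropped), and
identifier histories deduplicated into a time-ordered chronology.
Canonicalisation is idempotent; impossible or missing values are flagged
as missing rather than raised.
"""

from __future__ import annotations

import re
import unicodedata

import numpy as np
import pandas as pd

from .namebank import PostcodeLookup

__all__ = [
    "standardise_name",
    "standardise_name_part",
    "canonicalise_postcode",
    "build_identifier_chronology",
    "canonicalise_contacts",
    "canonicalise_census",
]

_NON_ALPHA = re.compile(r"[^A-Z]")
_NON_ALNUM = re.compile(r"[^A-Z0-9]")


def standardise_name_part(raw: str | None) -> str:
    """Canonicalise one name component.

    Upper-case, diacritics transliterated to ASCII, everything that is
    not a letter (spaces, hyphens, apostrophes) removed. Returns "" for
    missing/whitespace-only input.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    text = unicodedata.normalize("NFKD", str(raw))
    text = text.encode("ascii", "ignore").decode("ascii").upper()
    return _NON_ALPHA.sub("", text)


def standardise_name(raw_name: str | None) -> tuple[str, str]:
    """Split and canonicalise a raw name.

    Accepts either ``"Surname, Forename"`` or a bare surname; returns
    ``(surname_canonical, forename_canonical)`` with "" marking a missing
    component.
    """
    if raw_name is None or not str(raw_name).strip():
        return "", ""
    parts = str(raw_name).split(",", 1)
    surname = standardise_name_part(parts[0])
    forename = standardise_name_part(parts[1]) if len(parts) > 1 else ""
    return surname, forename


def canonicalise_postcode(
    raw: str | None, lookup: PostcodeLookup
) -> tuple[str, bool, str | None]:
    """Normalise a postcode and resolve its authority.

    Returns ``(canonical, valid, authority)``. The canonical form is
    upper-case with a single space before the 3-character inward part;
    codes absent from the look-up are flagged invalid with no authority.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or not str(raw).strip():
        return "", False, None
    compact = _NON_ALNUM.sub("", str(raw).upper())
    if len(compact) < 5:
        canonical = compact
    else:
        canonical = compact[:-3] + " " + compact[-3:]
    authority = lookup.authority(canonical)
    return canonical, authority is not None, authority


def build_identifier_chronology(contacts: pd.DataFrame) -> pd.DataFrame:
    """Reduce raw contact rows to a deduplicated, date-ordered chronology.

    ``contacts`` must carry a date column (``contact_date`` or
    ``census_year``) plus canonical identifier columns. Rows are sorted
    by date and consecutive rows with identical identifiers are merged,
    so every distinct (name, dob, postcode) state is retained once per
    episode. An ``empty_history`` flag is set when all identifiers are
    missing.
    """
    date_col = "contact_date" if "contact_date" in contacts.columns else "census_year"
    id_cols = [
        c for c in ("surname", "forename", "dob", "postcode") if c in contacts.columns
    ]
    chron = contacts.sort_values(date_col, kind="stable").reset_index(drop=True)
    key = chron[id_cols].astype(str)
    keep = (key != key.shift()).any(axis=1)
    keep.iloc[0] = True
    chron = chron[keep].reset_index(drop=True)
    filled = chron[id_cols].replace({"": None})
    chron["empty_history"] = filled.isna().all(axis=1).all()
    return chron


def _canonicalise_identifier_table(
    frame: pd.DataFrame, lookup: PostcodeLookup
) -> pd.DataFrame:
    out = frame.copy()
    out["surname"] = [standardise_name_part(x) for x in out["surname"]]
    out["forename"] = [standardise_name_part(x) for x in out["forename"]]
    pcs, valid, auth = zip(
        *(canonicalise_postcode(x, lookup) for x in out["postcode"])
    ) if len(out) else ((), (), ())
    out["postcode"] = pcs
    out["postcode_valid"] = valid
    out["authority"] = auth
    return out


def canonicalise_contacts(contacts: pd.DataFrame, lookup: PostcodeLookup) -> pd.DataFrame:
    """Canonical trial-side identifier table (one row per contact)."""
    return _canonicalise_identifier_table(contacts, lookup)


def canonicalise_census(census: pd.DataFrame, lookup: PostcodeLookup) -> pd.DataFrame:
    """Canonical register-side identifier table (one row per census segment)."""
    return _canonicalise_identifier_table(census, lookup)
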