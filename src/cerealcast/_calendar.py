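"""Calendar arithmetic for issue months, lead times and the growing season.

Months are 1-based calendar integers throughout.  A forecast issued in
calendar month ``m`` at lead ``lt`` verifies in month ``m_v = m + lt``,
circular over 12 (a December issue at lead 2 verifies in February of the
next calendar year).  The winter-cereal growing season runs October of the
year before harvest through June of the harvest year.
"""

from __future__ import annotations

import calendar

MONTH_ABBR = {
    1: "Jan", 2: "Feb", 3: "Mar", 4: "Apr", 5: "May", 6: "Jun",
    7: "Jul", 8: "Aug", 9: "Sep", 10: "Oct", 11: "Nov", 12: "Dec",
}
ABBR_MONTH = {v: k for k, v in MONTH_ABBR.items()}

#: calendar months of the growing season, in season order (Oct .. Jun)
SEASON_MONTHS = (10, 11, 12, 1, 2, 3, 4, 5, 6)

#: issue months of the forecast campaign (January .. June)
ISSUE_MONTHS = (1, 2, 3, 4, 5, 6)

MAX_LEAD = 6


def season_position(month: int) -> int:
    """Position of a calendar month within the Oct..Jun growing season (0-8).

    Raises ``ValueError`` for months outside the season (Jul-Sep).
    """
    try:
        return SEASON_MONTHS.index(month)
    except ValueError:
        raise ValueError(
            f"month {month} ({MONTH_ABBR.get(month, '?')}) is outside the "
            "Oct-Jun growing season"
        ) from None


def verification_month(issue_month: int, lead: int) -> int:
    """Calendar month verified by a forecast issued in ``issue_month`` at ``lead``."""
    if not 1 <= issue_month <= 12:
        raise ValueError(f"issue month must be 1-12, got {issue_month}")
    if lead < 0:
        raise ValueError(f"lead must be >= 0, got {lead}")
    return (issue_month + lead - 1) % 12 + 1


def verification_year(issue_year: int, issue_month: int, lead: int) -> int:
    """Calendar year of the verified month (wraps past December)."""
    return issue_year + (issue_month + lead - 1) // 12


def climate_year(harvest_year: int, month: int) -> int:
    """Calendar year holding ``month`` of the season harvested in ``harvest_year``.

    October-December belong to the calendar year before the harvest;
    January-June belong to the harvest year itself.
    """
    season_position(month)  # validates membership
    return harvest_year - 1 if month >= 10 else harvest_year


def month_before(month: int) -> int:
    """Previous calendar month, circular (Jan -> Dec)."""
    return (month - 2) % 12 + 1


def days_in_month(year: int, month: int) -> int:
    """Length of a calendar month, leap-aware."""
    return calendar.monthrange(year, month)[1]
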