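"""Reading and writing patent-record tables and tabular pipeline artifacts.

The expected input mirrors a Derwent-style export: a delimited text table
(comma or tab, sniffed from the header line) with one row per patent and,
at minimum, an identifier, a publication year, and the two free-text
abstract fields ``Novelty`` and ``Use``.  Column names are remappable via
``field_map`` because export schemas vary between tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["PatentRecord", "load_corpus", "write_table", "read_table", "records_to_frame"]

logger = logging.getLogger(__name__)

DEFAULT_YEAR_RANGE = (1950, 2030)

#: logical column -> default header name
DEFAULT_FIELD_MAP = {
    "patent_id": "patent_id",
    "year": "year",
    "novelty": "novelty",
    "use": "use",
    "title": "title",
}


@dataclass
class PatentRecord:
    """One patent: the unit of analysis.

    ``year`` is ``None`` when missing or outside the plausible range;
    such records stay in the network analysis but are excluded from the
    year-based trend series.
    """

    patent_id: str
    year: int | None
    novelty_text: str
    use_text: str
    title: str | None = None

    @property
    def analyzable(self) -> bool:
        return bool(self.novelty_text.strip() or self.use_text.strip())


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def load_corpus(
    path: str | Path,
    field_map: Mapping[str, str] | None = None,
    *,
    on_invalid: str = "drop",
    on_duplicate: str = "error",
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> list[PatentRecord]:
    """Read a patent table into records, preserving row order.

    Parameters
    ----------
    path:
        CSV or TSV file with a header line.
    field_map:
        Mapping from logical names (``patent_id``, ``year``, ``novelty``,
        ``use``, optionally ``title``) to the file's column names.
        Logical names missing from the map fall back to themselves.
    on_invalid:
        ``"drop"`` (default) logs and skips rows with neither text field;
        ``"keep"`` retains them.
    on_duplicate:
        ``"error"`` (default) raises on a repeated patent_id;
        ``"keep-first"`` keeps the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    if on_invalid not in ("drop", "keep"):
        raise ValueError(f"on_invalid must be 'drop' or 'keep', got {on_invalid!r}")
    if on_duplicate not in ("error", "keep-first"):
        raise ValueError(f"on_duplicate must be 'error' or 'keep-first', got {on_duplicate!r}")

    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    for logical in ("patent_id", "year", "novelty", "use"):
        if fmap[logical] not in df.columns:
            raise KeyError(
                f"column {fmap[logical]!r} (logical field {logical!r}) not in header: "
                f"{list(df.columns)}"
            )

    lo, hi = year_range
    records: list[PatentRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row[fmap["patent_id"]]).strip()
        if pid in seen:
            if on_duplicate == "error":
                raise ValueError(f"duplicate patent_id {pid!r}")
            logger.warning("duplicate patent_id %r: keeping first occurrence", pid)
            continue
        seen.add(pid)
        raw_year = str(row[fmap["year"]]).strip()
        year: int | None
        try:
            year = int(float(raw_year))
        except ValueError:
            year = None
        if year is not None and not (lo <= year <= hi):
            logger.warning("patent %r: year %s outside [%d, %d], flagged missing", pid, year, lo, hi)
            year = None
        title_col = fmap.get("title")
        rec = PatentRecord(
            patent_id=pid,
            year=year,
            novelty_text=str(row[fmap["novelty"]]),
            use_text=str(row[fmap["use"]]),
            title=str(row[title_col]) if title_col and title_col in df.columns else None,
        )
        if not rec.analyzable and on_invalid == "drop":
            logger.info("patent %r: both text fields empty, dropped", pid)
            continue
        records.append(rec)
    logger.info("loaded %d records from %s", len(records), path)
    return records


def records_to_frame(records: Iterable[PatentRecord]) -> pd.DataFrame:
    rows = [
        {
            "patent_id": r.patent_id,
            "year": "" if r.year is None else r.year,
            "novelty": r.novelty_text,
            "use": r.use_text,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["patent_id", "year", "novelty", "use"])


def write_table(
    rows: pd.DataFrame | Sequence[Mapping] | Sequence[Sequence],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write any tabular artifact as TSV with header.

    Accepts a DataFrame, a list of dicts, or a list of row tuples plus
    explicit ``columns``.  Round-trips through :func:`read_table`.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    elif columns is not None:
        df = pd.DataFrame(list(rows), columns=list(columns))
    else:
        df = pd.DataFrame(list(rows))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV artifact written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
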