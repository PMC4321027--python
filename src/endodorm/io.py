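"""Reading and writing the per-seed germination table.

The format is delimited text (comma by default), one row per seed per locus:

    experiment_id, seed_id, locus, endosperm_genotype, germination_day, status

``endosperm_genotype`` is a letter string (ddd/Ddd/DDd/DDD), a dose 0-3, or
NA; ``germination_day`` is a number or NA; ``status`` is G (germinated),
NG (nongerminated) or contaminated.  Contaminated rows are dropped before
analysis with a logged count -- they reduce the scored N but not the number
of seeds placed in the test.  Experiment metadata travels in ``#`` header
comments (``# n_total_tested=720`` etc.) so a written table reads back to an
identical population.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import math
from pathlib import Path
from typing import Optional, TextIO, Union

from .genotypes import (
    InvalidGenotypeError,
    NA_TOKEN,
    SeedPopulation,
    SeedRecord,
    endosperm_label,
    parse_endosperm_genotype,
)

__all__ = ["read_seed_table", "write_seed_table", "SeedTableError"]

logger = logging.getLogger("endodorm")

COLUMNS = (
    "experiment_id",
    "seed_id",
    "locus",
    "endosperm_genotype",
    "germination_day",
    "status",
)


class SeedTableError(ValueError):
    """Validation failure in a seed table, listing the offending rows."""


def _fmt_day(day: Optional[float]) -> str:
    if day is None:
        return NA_TOKEN
    return f"{day:g}"


def write_seed_table(
    pop: SeedPopulation,
    path: Union[str, Path, TextIO],
    delimiter: str = ",",
    genotype_as_dose: bool = False,
) -> None:
    """Serialize a population; genotypes default to letter strings."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "w", newline="")
        close = True
    else:
        handle = path
    try:
        handle.write(f"# n_total_tested={pop.n_total_tested}\n")
        handle.write(f"# end_day={pop.end_day:g}\n")
        handle.write(f"# counting_interval={pop.counting_interval:g}\n")
        if pop.after_ripening_days is not None:
            handle.write(f"# after_ripening_days={pop.after_ripening_days:g}\n")
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for rec in pop.records:
            status = "G" if rec.germinated else "NG"
            for locus, dose in rec.locus_doses.items():
                if dose is None:
                    geno = NA_TOKEN
                elif genotype_as_dose:
                    geno = str(dose)
                else:
                    geno = endosperm_label(dose)
                writer.writerow(
                    [
                        rec.experiment_id or pop.experiment_id,
                        rec.seed_id,
                        locus,
                        geno,
                        _fmt_day(rec.germination_day),
                        status,
                    ]
                )
    finally:
        if close:
            handle.close()


def read_seed_table(
    path: Union[str, Path, TextIO],
    delimiter: str = ",",
    n_total_tested: Optional[int] = None,
    end_day: Optional[float] = None,
    counting_interval: Optional[float] = None,
) -> SeedPopulation:
    """Parse and validate a seed table into a :class:`SeedPopulation`.

    Explicit keyword metadata overrides ``#`` header comments; when neither
    supplies ``n_total_tested`` the scored seed count is used.  Raises
    :class:`SeedTableError` listing every offending row for unknown genotype
    tokens, germination days outside the counting window, conflicting
    duplicate rows, or day/status contradictions.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "r", newline="")
        close = True
    else:
        handle = path
    try:
        meta: dict[str, float] = {}
        rows: list[dict[str, str]] = []
        header: Optional[list[str]] = None
        reader = csv.reader(handle, delimiter=delimiter)
        for lineno, raw in enumerate(reader, start=1):
            if not raw or (raw[0].startswith("#")):
                if raw and "=" in raw[0]:
                    key, _, val = raw[0].lstrip("# ").partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        pass
                continue
            if header is None:
                header = [c.strip() for c in raw]
                missing = set(COLUMNS) - set(header)
                if missing:
                    raise SeedTableError(
                        f"missing required columns: {sorted(missing)}"
                    )
                continue
            rows.append({"_line": str(lineno), **dict(zip(header, raw))})
        if header is None:
            raise SeedTableError("no header row found")

        end = end_day if end_day is not None else meta.get("end_day", 7.0)
        interval = (
            counting_interval
            if counting_interval is not None
            else meta.get("counting_interval", 1.0)
        )

        errors: list[str] = []
        seeds: dict[str, dict] = {}
        n_contaminated_rows = 0
        contaminated_ids: set[str] = set()
        for row in rows:
            line = row["_line"]
            sid = row["seed_id"].strip()
            status = row["status"].strip()
            if status.lower() == "contaminated":
                n_contaminated_rows += 1
                contaminated_ids.add(sid)
                continue
            if status not in ("G", "NG"):
                errors.append(f"line {line}: unknown status {status!r}")
                continue
            try:
                dose = parse_endosperm_genotype(row["endosperm_genotype"])
            except InvalidGenotypeError as exc:
                errors.append(f"line {line}: {exc}")
                continue
            day_tok = row["germination_day"].strip()
            day: Optional[float]
            if day_tok == "" or day_tok.upper() == NA_TOKEN:
                day = None
            else:
                try:
                    day = float(day_tok)
                except ValueError:
                    errors.append(f"line {line}: bad germination_day {day_tok!r}")
                    continue
                if not (2.0 <= day <= end):
                    errors.append(
                        f"line {line}: germination_day {day} outside the "
                        f"counting window [2, {end:g}]"
                    )
                    continue
            if status == "G" and day is None:
                errors.append(f"line {line}: status G but no germination_day")
                continue
            if status == "NG" and day is not None:
                errors.append(f"line {line}: status NG with a germination_day")
                continue
            entry = seeds.setdefault(
                sid,
                {
                    "experiment_id": row["experiment_id"].strip(),
                    "day": day,
                    "doses": {},
                },
            )
            if entry["day"] != day:
                errors.append(
                    f"line {line}: seed {sid!r} has conflicting germination days"
                )
                continue
            locus = row["locus"].strip()
            if locus in entry["doses"]:
                errors.append(
                    f"line {line}: duplicate row for seed {sid!r} locus {locus!r}"
                )
                continue
            entry["doses"][locus] = dose
        if errors:
            raise SeedTableError("; ".join(errors))

        records = [
            SeedRecord(
                seed_id=sid,
                locus_doses=entry["doses"],
                germination_day=entry["day"],
                experiment_id=entry["experiment_id"],
            )
            for sid, entry in seeds.items()
        ]
        if contaminated_ids:
            logger.info(
                "dropped %d contaminated seeds (%d rows)",
                len(contaminated_ids),
                n_contaminated_rows,
            )
        n_total = (
            n_total_tested
            if n_total_tested is not None
            else int(meta.get("n_total_tested", len(records)))
        )
        n_total = max(n_total, len(records))
        return SeedPopulation(
            records=records,
            n_total_tested=n_total,
            end_day=end,
            counting_interval=interval,
            after_ripening_days=meta.get("after_ripening_days"),
            experiment_id=records[0].experiment_id if records else "",
            n_contaminated=len(contaminated_ids),
        )
    finally:
        if close:
            handle.close()
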