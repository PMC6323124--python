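"""Person-table schema and referential-integrity validation."""

from __future__ import annotations

import pandas as pd

__all__ = ["validate_person_table"]

REQUIRED_COLUMNS = [
    "person_id", "family_id", "generation", "role", "sex", "birth_year",
    "death_age", "censor_age",
]

_GEN_ORDER = {"F1": 1, "F2": 2, "F3": 3}


def validate_person_table(table: pd.DataFrame | str) -> dict:
    """Check PersonRecord invariants and family-link integrity.

    Returns a machine-readable report: per-violation rule name, row ids, and
    counts.  Rules: unique person ids; at most one of death_age/censor_age;
    non-negative ages; birth_order <= sibship_size; mother/father ids resolve
    to rows of an earlier generation.
    """
    if isinstance(table, str):
        table = pd.read_csv(table)
    violations: list[dict] = []

    def add(rule: str, rows) -> None:
        rows = list(rows)
        if rows:
            violations.append({"rule": rule, "rows": rows, "count": len(rows)})

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        return {"ok": False, "violations": [
            {"rule": "missing_columns", "rows": missing_cols, "count": len(missing_cols)}]}

    dup = table["person_id"][table["person_id"].duplicated()]
    add("duplicate_person_id", dup.astype(int).tolist())

    both = table[table["death_age"].notna() & table["censor_age"].notna()]
    add("both_death_and_censor_age", both["person_id"].astype(int).tolist())

    for col in ("death_age", "censor_age"):
        neg = table[table[col].notna() & (table[col] < 0)]
        add(f"negative_{col}", neg["person_id"].astype(int).tolist())

    if {"birth_order", "sibship_size"}.issubset(table.columns):
        bad = table[
            table["birth_order"].notna() & table["sibship_size"].notna()
            & (table["birth_order"] > table["sibship_size"])
        ]
        add("birth_order_exceeds_sibship", bad["person_id"].astype(int).tolist())

    gen = table.set_index("person_id")["generation"].map(_GEN_ORDER)
    for col in ("mother_id", "father_id"):
        if col not in table.columns:
            continue
        linked = table[table[col].notna()]
        unresolved = linked[~linked[col].isin(table["person_id"])]
        add(f"unresolved_{col}", unresolved["person_id"].astype(int).tolist())
        resolved = linked[linked[col].isin(table["person_id"])]
        pgen = resolved[col].map(gen)
        cgen = resolved["generation"].map(_GEN_ORDER)
        bad = resolved[pgen >= cgen]
        add(f"{col}_generation_not_earlier", bad["person_id"].astype(int).tolist())

    return {"ok": not violations, "violations": violations,
            "n_rows": int(len(table))}
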