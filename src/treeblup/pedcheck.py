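"""Pedigree verification and polymix paternity assignment from a GRM.

A documented parent-offspring pair should show a genomic relationship
coefficient near 0.5 (higher under inbreeding); coefficients below a
confirmation floor (default 0.30) flag a pedigree error.  For polymix
families the true father is recovered as the pollen-pool candidate with
the highest relationship to the progeny, provided it clears the same
floor; families whose progeny all resolve to one sire become full-sib
families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import UNKNOWN, Pedigree, RelationshipMatrix

CONFIRM_MIN = 0.30


@dataclass
class ParentageReport:
    records: pd.DataFrame       # per progeny/parent: coefficient + verdict
    assignments: pd.DataFrame   # polymix progeny -> inferred sire
    summary: dict = field(default_factory=dict)

    @property
    def error_ids(self) -> list[str]:
        if self.records.empty:
            return []
        bad = self.records.loc[self.records["verdict"] == "error", "id"]
        return sorted(bad.unique())


def verify_parentage(g: RelationshipMatrix, ped: Pedigree,
                     confirm_min: float = CONFIRM_MIN) -> ParentageReport:
    """Check each genotyped progeny against its documented genotyped parents.

    Verdicts: ``confirmed`` (g >= confirm_min), ``error`` (below), and
    ``unresolved`` when the documented parent is not genotyped.  A progeny
    with any flagged documented parent counts as a pedigree error.
    """
    gset = set(g.ids)
    pos = {v: k for k, v in enumerate(g.ids)}
    rows = []
    for child in ped.ids:
        if child not in gset:
            continue
        sire, dam = ped.parents_of(child)
        for role, parent in (("sire", sire), ("dam", dam)):
            if parent == UNKNOWN:
                continue
            if parent not in gset:
                rows.append((child, role, parent, np.nan, "unresolved"))
                continue
            coef = float(g.values[pos[child], pos[parent]])
            verdict = "confirmed" if coef >= confirm_min else "error"
            rows.append((child, role, parent, coef, verdict))
    records = pd.DataFrame(
        rows, columns=["id", "role", "parent", "coefficient", "verdict"])
    n_err = len(set(records.loc[records["verdict"] == "error", "id"])) if len(rows) else 0
    summary = {
        "n_checked": len(set(records["id"])) if len(rows) else 0,
        "n_errors": n_err,
        "n_unresolved": int((records["verdict"] == "unresolved").sum()) if len(rows) else 0,
    }
    return ParentageReport(records=records, assignments=pd.DataFrame(
        columns=["id", "family", "sire", "coefficient"]), summary=summary)


def assign_polymix_fathers(g: RelationshipMatrix, ped: Pedigree,
                           pools: dict[str, list[str]],
                           confirm_min: float = CONFIRM_MIN) -> ParentageReport:
    """Infer polymix fathers as the best-related pool candidate per progeny.

    The inferred sire is ``argmax over pool of g(progeny, candidate)``
    when that maximum clears *confirm_min*, else the progeny stays
    unassigned.  Ties break toward the candidate with the higher average
    relationship to the progeny's maternal half-sibs, then by id.
    """
    for fam, pool in pools.items():
        if not pool:
            raise ValueError(f"empty pollen pool for family {fam!r}")
    gset = set(g.ids)
    pos = {v: k for k, v in enumerate(g.ids)}
    fam_members: dict[str, list[str]] = {}
    for child in ped.ids:
        fam = ped.family.get(child)
        if fam in pools:
            fam_members.setdefault(fam, []).append(child)
    rows = []
    for fam, members in fam_members.items():
        pool = [c for c in pools[fam]]
        missing = [c for c in pool if c not in gset]
        if missing:
            raise ValueError(f"pool candidates not genotyped: {missing[:3]}")
        for child in members:
            if child not in gset:
                continue
            coefs = {c: float(g.values[pos[child], pos[c]]) for c in pool}
            best = max(coefs.values())
            if best < confirm_min:
                rows.append((child, fam, UNKNOWN, best))
                continue
            tied = sorted(c for c, v in coefs.items() if abs(v - best) < 1e-12)
            if len(tied) > 1:
                sibs = [m for m in members if m != child and m in gset]

                def halfsib_score(c):
                    if not sibs:
                        return 0.0
                    return float(np.mean([g.values[pos[m], pos[c]] for m in sibs]))

                tied.sort(key=lambda c: (-halfsib_score(c), c))
            rows.append((child, fam, tied[0], best))
    assignments = pd.DataFrame(rows, columns=["id", "family", "sire", "coefficient"])
    resolved = assignments[assignments["sire"] != UNKNOWN]
    full_sib = [fam for fam, grp in resolved.groupby("family")
                if grp["sire"].nunique() == 1
                and len(grp) == len([m for m in fam_members[fam] if m in gset])]
    summary = {"n_progeny": len(assignments),
               "n_assigned": len(resolved),
               "full_sib_families": sorted(full_sib)}
    return ParentageReport(records=pd.DataFrame(
        columns=["id", "role", "parent", "coefficient", "verdict"]),
        assignments=assignments, summary=summary)


def corrected_pedigree(ped: Pedigree, report: ParentageReport) -> Pedigree:
    """Apply polymix assignments (and drop flagged parents) to a pedigree.

    Flagged-error parents are reset to unknown; assigned polymix sires
    are recorded.  This produces the input for a pedigree-corrected
    ABLUP.
    """
    df = ped.to_frame().set_index("id")
    for _, row in report.records.iterrows():
        if row["verdict"] == "error":
            df.loc[row["id"], row["role"]] = UNKNOWN
    for _, row in report.assignments.iterrows():
        if row["sire"] != UNKNOWN:
            df.loc[row["id"], "sire"] = row["sire"]
    df = df.reset_index()
    return Pedigree(df["id"], df["sire"], df["dam"],
                    family=ped.family, mating_type=ped.mating_type)
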