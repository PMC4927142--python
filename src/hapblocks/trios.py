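"""Trio validation of diplotype calls: Mendelian consistency and TDT."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .calling import DiplotypeCalls
from .io import PedigreeTable


class TrioError(ValueError):
    pass


def _call_lookup(calls: DiplotypeCalls) -> Dict[str, tuple]:
    return dict(zip(calls.sample_ids, calls.pairs))


def _consistent(child, father, mother) -> bool:
    return any(
        tuple(sorted((f, m))) == child for f in father for m in mother
    )


def mendelian_error_rate(calls: DiplotypeCalls, ped: PedigreeTable):
    """Fraction of evaluable trios whose child diplotype is non-Mendelian.

    A trio errs iff the child's unordered allele pair cannot be formed by
    taking one allele from each parent.  Trios with any member uncalled are
    excluded from the denominator.

    Returns ``(rate, flags)`` where ``flags`` is a DataFrame with one row
    per trio (child, evaluable, error).
    """
    lookup = _call_lookup(calls)
    rows = []
    n_err = n_eval = 0
    for child_id, father_id, mother_id in ped.trios:
        members = [lookup.get(i) for i in (child_id, father_id, mother_id)]
        if any(m is None for m in members):
            rows.append((child_id, False, False))
            continue
        child, father, mother = members
        err = not _consistent(child, father, mother)
        n_eval += 1
        n_err += err
        rows.append((child_id, True, err))
    if n_eval == 0:
        raise TrioError("no trio has all three members called")
    flags = pd.DataFrame(rows, columns=["child", "evaluable", "error"])
    return n_err / n_eval, flags


@dataclass
class TDTResult:
    """Transmission disequilibrium of one allele from heterozygous parents."""

    allele: str
    b: int  # transmissions
    c: int  # non-transmissions
    chi_square: float
    p_value: float
    n_trios: int
    undefined: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def tdt(calls: DiplotypeCalls, ped: PedigreeTable, allele: str) -> TDTResult:
    """Transmission disequilibrium test for one allele, trios folded binary.

    Multi-allelic diplotypes are folded to carrier dose of the target allele
    (0/1/2).  Only heterozygous (dose-1) parents are informative; each
    contributes one transmission or non-transmission.  Mendelian-inconsistent
    trios are excluded.  ``chi_square = (b − c)² / (b + c)`` with a 1-df
    reference; ``b + c = 0`` yields an undefined (flagged) result.
    """
    if allele not in calls.allele_names:
        raise TrioError(f"allele {allele!r} not in declared set {calls.allele_names}")
    lookup = _call_lookup(calls)
    b = c = n_used = 0
    for child_id, father_id, mother_id in ped.trios:
        members = [lookup.get(i) for i in (child_id, father_id, mother_id)]
        if any(m is None for m in members):
            continue
        child, father, mother = members
        if not _consistent(child, father, mother):
            continue
        d_child = child.count(allele)
        d_f, d_m = father.count(allele), mother.count(allele)
        n_het = (d_f == 1) + (d_m == 1)
        if n_het == 0:
            continue
        # transmissions of the allele from het parents: child copies minus
        # the copies forced by homozygous parents
        t = d_child - (d_f == 2) - (d_m == 2)
        if not 0 <= t <= n_het:
            continue  # unreachable under folded Mendelian consistency
        b += t
        c += n_het - t
        n_used += 1
    if b + c == 0:
        return TDTResult(allele, 0, 0, float("nan"), float("nan"), n_used,
                         undefined=True)
    chi2 = (b - c) ** 2 / (b + c)
    return TDTResult(allele, b, c, float(chi2),
                     float(chi2_dist.sf(chi2, df=1)), n_used)


def tdt_all(calls: DiplotypeCalls, ped: PedigreeTable) -> pd.DataFrame:
    """Per-allele TDT over the declared allele set."""
    return pd.concat([tdt(calls, ped, a).to_frame() for a in calls.allele_names],
                     ignore_index=True)
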