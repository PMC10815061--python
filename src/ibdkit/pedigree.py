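"""Pedigree structures, affected-pair enumeration and Mendelian checks.

A pedigree is read from standard 6-column PED text (family, individual,
father, mother, sex, phenotype).  Phenotype coding follows the usual PED
dialect: ``2`` = affected, ``1`` = unaffected, ``0``/``-9`` = unknown
(treated as unaffected when enumerating affected pairs).  ``0`` in a parent
column denotes an absent parent; an individual whose parents are both absent
(or not genotyped) is a founder.

Genotypes throughout this package are unphased diploid allele-index pairs,
e.g. ``(0, 1)`` for a heterozygote, or ``None`` when the call is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

__all__ = [
    "Member",
    "Pedigree",
    "PedigreeError",
    "parse_pedigree",
    "affected_pairs",
    "mendelian_consistent",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

Genotype = Optional[tuple[int, int]]


class PedigreeError(ValueError):
    """Malformed pedigree input (duplicate ids, dangling parents, cycles...)."""


@dataclass(frozen=True)
class Member:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` when the parent is absent.
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = UNKNOWN
    affected: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("member id must be non-empty")
        if self.id in (self.father_id, self.mother_id):
            raise PedigreeError(f"member {self.id!r} is listed as its own parent")


@dataclass
class Pedigree:
    """An ordered collection of :class:`Member` with resolved parent links."""

    members: list[Member]
    _index: dict[str, Member] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for m in self.members:
            if m.id in self._index:
                raise PedigreeError(f"duplicate member id {m.id!r}")
            self._index[m.id] = m
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS from every member through declared parent links.
        state: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(mid: str) -> None:
            if mid not in self._index:
                return
            if state.get(mid) == 0:
                raise PedigreeError(f"pedigree cycle involving {mid!r}")
            if state.get(mid) == 1:
                return
            state[mid] = 0
            m = self._index[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            state[mid] = 1

        for m in self.members:
            visit(m.id)

    # -- lookups ---------------------------------------------------------

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._index

    def __len__(self) -> int:
        return len(self.members)

    def get(self, member_id: str) -> Member:
        try:
            return self._index[member_id]
        except KeyError:
            raise PedigreeError(f"unknown member id {member_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def affected_ids(self) -> list[str]:
        return [m.id for m in self.members if m.affected]

    def unaffected_ids(self) -> list[str]:
        return [m.id for m in self.members if not m.affected]

    def parents_of(self, member_id: str) -> tuple[Optional[str], Optional[str]]:
        """Declared (father, mother) ids; ``None`` for absent or undeclared."""
        m = self.get(member_id)
        father = m.father_id if m.father_id in self._index else None
        mother = m.mother_id if m.mother_id in self._index else None
        return father, mother

    def is_founder(self, member_id: str) -> bool:
        """True when neither parent resolves to a pedigree member."""
        father, mother = self.parents_of(member_id)
        return father is None and mother is None

    def founders(self) -> list[str]:
        return [m.id for m in self.members if self.is_founder(m.id)]

    def summary(self) -> str:
        lines = [f"Pedigree with {len(self)} members "
                 f"({len(self.affected_ids())} affected, {len(self.founders())} founders)"]
        for m in self.members:
            status = "affected" if m.affected else "unaffected"
            parents = f"{m.father_id or '-'} x {m.mother_id or '-'}"
            lines.append(f"  {m.id:<8s} {m.sex:<8s} {status:<10s} parents: {parents}")
        return "\n".join(lines)


_SEX_CODES = {"1": MALE, "2": FEMALE}


def parse_pedigree(text: str, strict: bool = True) -> Pedigree:
    """Parse PED-format text into a :class:`Pedigree`.

    Parameters
    ----------
    text
        PED content: one member per line, >= 6 whitespace-separated columns
        (family, id, father, mother, sex, phenotype); ``#`` comments allowed.
    strict
        When True (default), a parent id that is neither ``"0"`` nor a
        declared member raises :class:`PedigreeError`.  When False the
        reference is dropped and the member becomes a founder with an
        un-genotyped parent.
    """
    rows: list[tuple[str, str, str, str, str]] = []
    ids: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(
                f"line {lineno}: expected >= 6 columns, got {len(cols)}")
        _fam, iid, fid, mid, sex, pheno = cols[:6]
        if iid in ids:
            raise PedigreeError(f"duplicate member id {iid!r}")
        ids.add(iid)
        rows.append((iid, fid, mid, sex, pheno))
    if not rows:
        raise PedigreeError("no pedigree records found")

    members: list[Member] = []
    for iid, fid, mid, sex, pheno in rows:
        def resolve(pid: str) -> Optional[str]:
            if pid == "0":
                return None
            if pid not in ids:
                if strict:
                    raise PedigreeError(
                        f"member {iid!r} references undeclared parent {pid!r}")
                return None  # lenient: un-genotyped founder parent
            return pid

        members.append(Member(
            id=iid,
            father_id=resolve(fid),
            mother_id=resolve(mid),
            sex=_SEX_CODES.get(sex, UNKNOWN),
            affected=(pheno == "2"),
        ))
    return Pedigree(members)


def affected_pairs(
    ped: Pedigree,
    sample_ids: Optional[Iterable[str]] = None,
) -> list[tuple[str, str]]:
    """All C(k, 2) unordered pairs of affected members, lexicographic.

    ``sample_ids`` restricts the enumeration to members with genotype data
    (e.g. samples present in the VCF).  Fewer than two affected members
    yields an empty list.
    """
    affected = ped.affected_ids()
    if sample_ids is not None:
        allowed = set(sample_ids)
        affected = [a for a in affected if a in allowed]
    return list(combinations(sorted(affected), 2))


def _validate_genotype(gt: Genotype, who: str) -> Genotype:
    if gt is None:
        return None
    if len(gt) != 2:
        raise ValueError(f"{who} genotype must be diploid, got {gt!r}")
    if any(a is None or a < 0 for a in gt):
        return None  # partial/missing call treated as missing
    return tuple(gt)  # type: ignore[return-value]


def mendelian_consistent(
    child: Genotype,
    father: Genotype = None,
    mother: Genotype = None,
) -> bool:
    """Can the child's genotype arise by biparental transmission?

    With both parents available the check enumerates one-allele-per-parent
    transmissions; with one parent, the child must share at least one allele
    with that parent.  Any missing genotype (child or both parents) makes the
    site untestable and the check passes — the "no Mendelian error" filter
    can only be asserted where data exist.
    """
    child = _validate_genotype(child, "child")
    father = _validate_genotype(father, "father")
    mother = _validate_genotype(mother, "mother")

    if child is None:
        return True
    if father is not None and mother is not None:
        target = sorted(child)
        return any(
            sorted((a, b)) == target for a in father for b in mother
        )
    single = father if father is not None else mother
    if single is None:
        return True
    return bool(set(child) & set(single))
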