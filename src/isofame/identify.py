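"""Retention-time assignment of detected peaks to library compounds.

Matching is greedy by ascending |RT offset|: each accepted peak may take
the nearest library entry within tolerance, and each library entry is used
at most once.  A peak exactly equidistant between two entries is flagged
ambiguous and left unassigned.  Greedy matching is transparent to audit;
on realistic chromatograms (library spacing well above the tolerance) it
coincides with the exhaustive minimum-total-offset assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .peaks import Peak, merge_coeluting
from .trace_io import CompoundLibrary, ConfigError

__all__ = ["FameAssignment", "assign_compounds", "apply_merge_rules", "merge_group_name"]


@dataclass(frozen=True)
class FameAssignment:
    peak_id: int               # index into the peak list
    compound: str | None       # library name, or None if unassigned
    rt_offset: float           # peak RT - library RT, s (0 if unassigned)
    ambiguous: bool = False


def assign_compounds(
    peaks: list[Peak],
    library: CompoundLibrary,
    tolerance: float = 10.0,
) -> list[FameAssignment]:
    """Match peaks to library retention times within ``tolerance`` seconds."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    entries = list(library)
    candidates = []  # (|offset|, peak index, entry index, offset)
    ambiguous: set[int] = set()
    for pi, peak in enumerate(peaks):
        offsets = [(abs(peak.t_apex - e.rt), ei, peak.t_apex - e.rt) for ei, e in enumerate(entries)]
        offsets = [o for o in offsets if o[0] <= tolerance]
        if not offsets:
            continue
        offsets.sort(key=lambda o: o[0])
        if len(offsets) >= 2 and offsets[0][0] == offsets[1][0]:
            ambiguous.add(pi)  # tie: equidistant between two entries
            continue
        for dist, ei, off in offsets:
            candidates.append((dist, pi, ei, off))
    candidates.sort(key=lambda c: (c[0], c[1]))
    taken_peaks: dict[int, tuple[int, float]] = {}
    taken_entries: set[int] = set()
    for dist, pi, ei, off in candidates:
        if pi in taken_peaks or ei in taken_entries:
            continue
        taken_peaks[pi] = (ei, off)
        taken_entries.add(ei)
    out = []
    for pi in range(len(peaks)):
        if pi in taken_peaks:
            ei, off = taken_peaks[pi]
            out.append(FameAssignment(pi, entries[ei].name, off))
        else:
            out.append(FameAssignment(pi, None, 0.0, ambiguous=pi in ambiguous))
    return out


def merge_group_name(members: list[str]) -> str:
    """Display name for a merged coelution group, e.g. C18:1n-7 + C18:1n-9 -> C18:1."""
    prefix = members[0]
    for name in members[1:]:
        while not name.startswith(prefix):
            prefix = prefix[:-1]
    stripped = prefix.rstrip("n-")
    return stripped if stripped else " + ".join(members)


def apply_merge_rules(
    assignments: list[FameAssignment],
    peaks: list[Peak],
    rules: list[list[str]],
    library: CompoundLibrary | None = None,
) -> tuple[list[FameAssignment], list[Peak]]:
    """Merge peaks assigned to compounds of one coelution rule group.

    Each rule names >= 2 library compounds (e.g. the C18:1 isomers that the
    column cannot separate); their peaks, which must be contiguous in
    elution order, are combined via :func:`isofame.peaks.merge_coeluting`
    and renamed to the group name.  Returns the rewritten (assignments,
    peaks) pair.
    """
    for rule in rules:
        if len(rule) < 2:
            raise ConfigError("each merge rule must name at least 2 compounds")
        if library is not None:
            unknown = [name for name in rule if name not in library.names]
            if unknown:
                raise ConfigError(f"merge rule names unknown compound(s): {unknown}")
    peaks = list(peaks)
    assignments = list(assignments)
    for rule in rules:
        member_ids = [a.peak_id for a in assignments if a.compound in rule]
        if len(member_ids) < 2:
            continue  # 0 or 1 member present: nothing to merge
        merged = merge_coeluting(peaks, member_ids)
        name = merge_group_name(sorted(rule))
        keep_peaks, keep_assignments = [], []
        inserted = False
        for a in sorted(assignments, key=lambda a: peaks[a.peak_id].t_start):
            if a.peak_id in member_ids:
                if not inserted:
                    keep_peaks.append(merged)
                    keep_assignments.append(
                        FameAssignment(len(keep_peaks) - 1, name, 0.0)
                    )
                    inserted = True
                continue
            keep_peaks.append(peaks[a.peak_id])
            keep_assignments.append(
                FameAssignment(len(keep_peaks) - 1, a.compound, a.rt_offset, a.ambiguous)
            )
        peaks, assignments = keep_peaks, keep_assignments
    return assignments, peaks
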