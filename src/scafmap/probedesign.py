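"""Targeted-capture probe candidate cascade.

From each informative polymorphism, a 201 bp flanking segment centred on
the site is extracted (skipped when the site is within 100 bp of a scaffold
end), screened for genome-wide uniqueness against a BLAST-style hit table
(unique = exactly one hit at E <= 1e-50 and identity >= 85%), and 100 bp
probe windows overlapping the site are scored and filtered:

* standard stringency: GC >= 0.30, >= 97 homozygous sites of 100, no
  homopolymer run longer than 5 bp, no N bases;
* relaxed (rescue) stringency: GC >= 0.25, >= 96 homozygous sites, runs up
  to 8 bp.

Per-scaffold caps are tiered by length (3 probes under 100 kb, 3 per half
for 100-200 kb, 3 per third above 200 kb); the final selection keeps one
probe for scaffolds under 100 kb and up to three for larger scaffolds,
within a total budget, and a rescue pass re-runs relaxed filtering for
scaffolds over 100 kb that ended up with no probes.  Candidate ranking is
ordinal: uniqueness at a 75% identity screen first, then centring on the
target polymorphism, then few overlapping heterozygous sites, then
proximity to the scaffold middle.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProbeCandidate",
    "read_fasta",
    "write_probe_fasta",
    "read_hit_table",
    "exact_hit_table",
    "screen_uniqueness",
    "extract_flanks",
    "build_candidates",
    "filter_probe",
    "cap_and_select",
    "final_selection",
    "design_probes",
]

PROBE_LEN = 100
FLANK_LEN = 201

HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]


@dataclasses.dataclass
class ProbeCandidate:
    scaffold_id: str
    start_1based: int  # on the scaffold
    sequence: str
    gc_fraction: float
    homozygous_site_count: int
    max_homopolymer_run: int
    n_count: int
    target_polymorphism_offset: int  # 0-based offset of the target site in the probe
    het_overlap: int = 0
    unique_at_75: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LEN:
            raise ValueError("probe length must be exactly 100 bp")


def read_fasta(path) -> dict[str, str]:
    """Scaffold sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_probe_fasta(probes: Sequence["ProbeCandidate"], path) -> None:
    """Selected probes as FASTA, ids ``<scaffold>:<start>`` (1-based)."""
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.scaffold_id}:{p.start_1based}", description="")
        for p in probes
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) hit table."""
    return pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)


def exact_hit_table(fragments: Mapping[str, str], genome: Mapping[str, str]) -> pd.DataFrame:
    """Exact-duplication screen for synthetic genomes.

    Emulates a BLAST self-search by exact substring matching: each fragment
    yields one hit row (identity 100, E = 0) per occurrence across the
    genome sequences.
    """
    rows = []
    for qid, frag in fragments.items():
        for sid, seq in genome.items():
            start = seq.find(frag)
            while start != -1:
                rows.append(
                    (qid, sid, 100.0, len(frag), 0, 0, 1, len(frag),
                     start + 1, start + len(frag), 0.0, 2.0 * len(frag))
                )
                start = seq.find(frag, start + 1)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def screen_uniqueness(
    fragment_ids: Iterable[str],
    hits: pd.DataFrame,
    evalue_max: float = 1e-50,
    identity_min: float = 85.0,
) -> pd.DataFrame:
    """Flag each fragment unique / non-unique / anomalous.

    A fragment is unique iff exactly one hit passes the E-value and identity
    thresholds (that hit being the expected self-hit).  Zero passing hits is
    anomalous, since a self-hit should always be present.
    """
    passing = hits[
        (hits["e_value"] <= evalue_max) & (hits["percent_identity"] >= identity_min)
    ]
    counts = passing.groupby("query_id").size()
    rows = []
    for fid in fragment_ids:
        n = int(counts.get(fid, 0))
        status = "anomalous" if n == 0 else ("unique" if n == 1 else "non-unique")
        rows.append((fid, n, status == "unique", status))
    return pd.DataFrame(rows, columns=["fragment_id", "n_hits", "is_unique", "status"])


def extract_flanks(position_1based: int, scaffold_sequence: str) -> str | None:
    """201 bp segment centred on the polymorphism, or None near an edge."""
    half = (FLANK_LEN - 1) // 2
    if position_1based - half < 1 or position_1based + half > len(scaffold_sequence):
        return None
    return scaffold_sequence[position_1based - half - 1: position_1based + half]


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def build_candidates(
    scaffold_id: str,
    site_position_1based: int,
    segment: str,
    het_offsets: Sequence[int] = (),
    scaffold_sequence_length: int | None = None,
    unique_at_75: bool = True,
) -> list[ProbeCandidate]:
    """All 100 bp windows of the 201 bp segment that overlap the centre site.

    ``het_offsets`` are 0-based offsets within the segment of sites known to
    be heterozygous in either parent (the centre site, offset 100, counts as
    heterozygous whether listed or not).
    """
    if len(segment) != FLANK_LEN:
        raise ValueError("segment must be exactly 201 bp")
    centre = (FLANK_LEN - 1) // 2
    hets = set(het_offsets) | {centre}
    out = []
    seg_start_on_scaffold = site_position_1based - centre - 1  # 0-based
    for s in range(centre - PROBE_LEN + 1, centre + 1):
        if s < 0 or s + PROBE_LEN > FLANK_LEN:
            continue
        window = segment[s: s + PROBE_LEN]
        het_in = [h for h in hets if s <= h < s + PROBE_LEN]
        gc = (window.count("G") + window.count("C")) / PROBE_LEN
        out.append(
            ProbeCandidate(
                scaffold_id=scaffold_id,
                start_1based=seg_start_on_scaffold + s + 1,
                sequence=window,
                gc_fraction=gc,
                homozygous_site_count=PROBE_LEN - len(het_in),
                max_homopolymer_run=_max_run(window),
                n_count=window.count("N"),
                target_polymorphism_offset=centre - s,
                het_overlap=len(het_in) - 1,
                unique_at_75=unique_at_75,
            )
        )
    return out


_THRESHOLDS = {
    "standard": {"gc": 0.30, "homozygous": 97, "run": 5},
    "relaxed": {"gc": 0.25, "homozygous": 96, "run": 8},
}


def filter_probe(candidate: ProbeCandidate, stringency: str = "standard") -> tuple[bool, list[str]]:
    """Pass/fail with reasons against one stringency tier."""
    t = _THRESHOLDS[stringency]
    reasons = []
    if candidate.gc_fraction < t["gc"] - 1e-12:
        reasons.append("GC")
    if candidate.homozygous_site_count < t["homozygous"]:
        reasons.append("homozygous_sites")
    if candidate.max_homopolymer_run > t["run"]:
        reasons.append("homopolymer")
    if candidate.n_count > 0:
        reasons.append("N_bases")
    return (len(reasons) == 0, reasons)


def _score_key(c: ProbeCandidate, scaffold_length: int):
    mid = scaffold_length / 2.0
    probe_mid = c.start_1based + PROBE_LEN / 2.0
    return (
        0 if c.unique_at_75 else 1,
        abs(c.target_polymorphism_offset - (PROBE_LEN - 1) / 2.0),
        c.het_overlap,
        abs(probe_mid - mid),
        c.start_1based,
    )


def cap_and_select(
    candidates: Sequence[ProbeCandidate],
    scaffold_length: int,
    per_window: int = 3,
) -> list[ProbeCandidate]:
    """Tiered per-scaffold cap: 3 / 3-per-half / 3-per-third by length.

    Windows are halves or thirds by floor division of the scaffold length;
    a probe belongs to the window containing its start.
    """
    if scaffold_length < 100_000:
        n_windows = 1
    elif scaffold_length <= 200_000:
        n_windows = 2
    else:
        n_windows = 3
    win_len = max(scaffold_length // n_windows, 1)
    by_window: dict[int, list[ProbeCandidate]] = {}
    for c in candidates:
        w = min((c.start_1based - 1) // win_len, n_windows - 1)
        by_window.setdefault(w, []).append(c)
    out = []
    for w in sorted(by_window):
        ranked = sorted(by_window[w], key=lambda c: _score_key(c, scaffold_length))
        out.extend(ranked[:per_window])
    return out


def final_selection(
    candidates_by_scaffold: Mapping[str, Sequence[ProbeCandidate]],
    scaffold_lengths: Mapping[str, int],
    budget: int,
) -> list[ProbeCandidate]:
    """Pick the synthesis set: 1 probe under 100 kb, up to 3 above, in budget.

    Scaffolds are served largest-first; if the budget cannot cover one probe
    per scaffold a warning reports the shortfall.
    """
    order = sorted(
        candidates_by_scaffold,
        key=lambda s: (-scaffold_lengths.get(s, 0), s),
    )
    if budget < len([s for s in order if candidates_by_scaffold[s]]):
        warnings.warn("probe budget below one per scaffold; coverage is partial")
    chosen: list[ProbeCandidate] = []
    # first pass: one probe per scaffold
    extras: list[ProbeCandidate] = []
    for scaf in order:
        cands = sorted(
            candidates_by_scaffold[scaf],
            key=lambda c: _score_key(c, scaffold_lengths.get(scaf, 0)),
        )
        if not cands:
            continue
        if len(chosen) < budget:
            chosen.append(cands[0])
        if scaffold_lengths.get(scaf, 0) >= 100_000:
            extras.extend(cands[1:3])
    for c in extras:
        if len(chosen) >= budget:
            break
        chosen.append(c)
    return chosen


def design_probes(
    scaffold_sequences: Mapping[str, str],
    sites: pd.DataFrame,  # scaffold_id, position (1-based), het flag columns optional
    het_positions: Mapping[str, Sequence[int]] | None = None,
    uniqueness: pd.DataFrame | None = None,
    budget: int = 1000,
) -> tuple[list[ProbeCandidate], pd.DataFrame]:
    """End-to-end cascade: flanks, filters, caps, rescue, final selection.

    ``het_positions`` maps scaffold -> 1-based heterozygous positions (for
    the homozygous-site count); ``uniqueness`` is the output of
    :func:`screen_uniqueness` keyed by "scaffold:position" fragment ids.
    Returns the selected probes and a per-scaffold accounting table.
    """
    het_positions = het_positions or {}
    unique_lookup = {}
    if uniqueness is not None:
        unique_lookup = dict(zip(uniqueness["fragment_id"], uniqueness["is_unique"]))

    retained: dict[str, list[ProbeCandidate]] = {}
    accounting = []
    for scaf, sub in sites.groupby("scaffold_id"):
        seq = scaffold_sequences.get(scaf)
        if seq is None:
            continue
        length = len(seq)
        hets = het_positions.get(scaf, ())

        def candidates_at(stringency: str) -> list[ProbeCandidate]:
            found: list[ProbeCandidate] = []
            for pos in sorted(sub["position"].astype(int)):
                frag_id = f"{scaf}:{pos}"
                if unique_lookup and not unique_lookup.get(frag_id, True):
                    continue
                segment = extract_flanks(pos, seq)
                if segment is None:
                    continue
                offs = [h - pos + 100 for h in hets if 0 <= h - pos + 100 < FLANK_LEN]
                for c in build_candidates(scaf, pos, segment, offs):
                    if filter_probe(c, stringency)[0]:
                        found.append(c)
            return found

        cands = candidates_at("standard")
        capped = cap_and_select(cands, length)
        rescued = False
        if not capped and length > 100_000:
            capped = cap_and_select(candidates_at("relaxed"), length)
            rescued = bool(capped)
        retained[scaf] = capped
        accounting.append((scaf, length, len(cands), len(capped), rescued))

    probes = final_selection(retained, {s: len(q) for s, q in scaffold_sequences.items()}, budget)
    table = pd.DataFrame(
        accounting,
        columns=["scaffold_id", "length_bp", "n_passing", "n_capped", "rescued"],
    )
    return probes, table


def probes_frame(probes: Sequence[ProbeCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.scaffold_id, p.start_1based, p.sequence, p.gc_fraction,
             p.homozygous_site_count, p.max_homopolymer_run, p.target_polymorphism_offset)
            for p in probes
        ],
        columns=[
            "scaffold_id", "start_1based", "sequence", "gc_fraction",
            "homozygous_sites", "max_homopolymer_run", "target_offset",
        ],
    )
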