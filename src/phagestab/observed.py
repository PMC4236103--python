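"""Observed substitution sets and cumulative stability trajectories.

Two sources of substitutions fixed in real populations are supported:

* **wild phage** — substitutions called by comparing aligned homologous
  protein sequences against their column-wise consensus (a simple proxy
  for the ancestral sequence);
* **laboratory adaptations** — an experiment registry of (possibly
  branching) adaptation experiments, each a rooted tree of segments
  carrying substitution lists, with a temperature class (high ≥ 42 °C,
  normal ≤ 37 °C, else variable) and a flag for whether the line began
  with the reference ancestor.

Cumulative trajectories sum ΔΔG_fold and ΔΔG_bind along root-to-segment
paths, starting at (0, 0).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml

from .ddg_io import DdgTable
from .neighborhood import AMINO_ACIDS, SubstitutionKey

TemperatureClass = Literal["high", "normal", "variable"]

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_substitution(text: str) -> SubstitutionKey:
    """Parse compact notation like ``A123T`` (aa_from, site, aa_to)."""
    m = _SUB_RE.match(text.strip().upper())
    if not m:
        raise ValueError(f"cannot parse substitution {text!r}; expected e.g. 'A123T'")
    return SubstitutionKey(int(m.group(2)), m.group(1), m.group(3)).validate()


def classify_temperature(celsius: float) -> TemperatureClass:
    """Temperature class from °C: high ≥ 42, normal ≤ 37, otherwise variable."""
    if celsius >= 42.0:
        return "high"
    if celsius <= 37.0:
        return "normal"
    return "variable"


@dataclass
class Segment:
    id: str
    parent: str | None
    substitutions: list[SubstitutionKey] = field(default_factory=list)
    time: float | None = None


@dataclass
class Experiment:
    """One laboratory adaptation: a rooted tree of segments."""

    id: str
    temperature_class: TemperatureClass
    ancestor_start: bool = True
    source_label: str = ""
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_tree()

    def _check_tree(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError(f"experiment {self.id}: duplicate segment ids")
        roots = [s for s in self.segments if s.parent is None]
        if self.segments and len(roots) != 1:
            raise ValueError(f"experiment {self.id}: need exactly one root segment")
        known = set(ids)
        for s in self.segments:
            if s.parent is not None and s.parent not in known:
                raise ValueError(f"experiment {self.id}: unknown parent {s.parent!r}")
        # reject cycles: every segment must reach the root
        parent_of = {s.id: s.parent for s in self.segments}
        for s in self.segments:
            seen = set()
            cur: str | None = s.id
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"experiment {self.id}: cycle at segment {cur!r}")
                seen.add(cur)
                cur = parent_of[cur]

    def all_substitutions(self) -> set[SubstitutionKey]:
        return {k for s in self.segments for k in s.substitutions}


@dataclass(frozen=True)
class TrajectoryPoint:
    segment_id: str
    cumulative_ddg_fold: float
    cumulative_ddg_bind: float


class ConsensusTieError(ValueError):
    """A column's most frequent residue is not unique."""


def consensus_sequence(
    seqs: Iterable[str], tie_policy: Literal["error", "first-in-alphabet"] = "error"
) -> str:
    """Column-wise consensus of aligned, gap-free protein sequences."""
    seqs = [str(s).upper() for s in seqs]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not all the same length")
    for s in seqs:
        bad = set(s) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residue characters: {sorted(bad)}")
    out = []
    for col in range(length):
        counts = Counter(s[col] for s in seqs)
        top = max(counts.values())
        winners = sorted(aa for aa, c in counts.items() if c == top)
        if len(winners) > 1 and tie_policy == "error":
            raise ConsensusTieError(
                f"consensus tie at column {col + 1}: {winners} each occur {top} times"
            )
        out.append(winners[0])
    return "".join(out)


def consensus_observed_substitutions(
    seqs: Iterable[str], tie_policy: Literal["error", "first-in-alphabet"] = "error"
) -> set[SubstitutionKey]:
    """Substitutions separating each sequence from the consensus.

    Every (sequence, column) residue differing from the column consensus
    yields one consensus→variant key; duplicates across sequences
    collapse. Sites are numbered 1..L over the alignment columns.

    Applied to a set of wild phage coat-protein homologs (e.g. the 19
    φX174-like F sequences), this yields the wild-phage observed
    substitution set, treating the consensus as a putative ancestor.
    """
    seqs = [str(s).upper() for s in seqs]
    cons = consensus_sequence(seqs, tie_policy=tie_policy)
    return {
        SubstitutionKey(col + 1, cons[col], s[col])
        for s in seqs
        for col in range(len(cons))
        if s[col] != cons[col]
    }


def read_homolog_fasta(path: str) -> list[str]:
    """Aligned homolog protein sequences from FASTA, in file order."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")]


def cumulative_trajectory(exp: Experiment, table: DdgTable) -> list[TrajectoryPoint]:
    """Cumulative (ΔΔG_fold, ΔΔG_bind) at each segment of an experiment.

    Each segment's point is its parent's point plus the sum over the
    segment's substitution list; the (implicit) ancestor sits at (0, 0).
    An experiment with no segments yields the single point (0, 0).
    """
    if not exp.segments:
        return [TrajectoryPoint("root", 0.0, 0.0)]
    sums: dict[str, tuple[float, float]] = {}
    points: list[TrajectoryPoint] = []

    def segment_sum(seg: Segment) -> tuple[float, float]:
        f = b = 0.0
        for key in seg.substitutions:
            try:
                row = table.lookup(key)
            except KeyError as exc:
                raise KeyError(
                    f"experiment {exp.id}, segment {seg.id}: {exc.args[0]}"
                ) from None
            f += float(row["ddg_fold"])
            b += float(row["ddg_bind"])
        return f, b

    by_id = {s.id: s for s in exp.segments}

    def point_of(seg_id: str) -> tuple[float, float]:
        if seg_id in sums:
            return sums[seg_id]
        seg = by_id[seg_id]
        pf, pb = (0.0, 0.0) if seg.parent is None else point_of(seg.parent)
        sf, sb = segment_sum(seg)
        sums[seg_id] = (pf + sf, pb + sb)
        return sums[seg_id]

    for seg in exp.segments:
        f, b = point_of(seg.id)
        points.append(TrajectoryPoint(seg.id, f, b))
    return points


def trajectory_table(experiments: Iterable[Experiment], table: DdgTable) -> pd.DataFrame:
    """Trajectories for many experiments as a flat TSV-ready frame."""
    rows = []
    for exp in experiments:
        for pt in cumulative_trajectory(exp, table):
            rows.append(
                {
                    "experiment": exp.id,
                    "segment": pt.segment_id,
                    "cum_ddg_fold": pt.cumulative_ddg_fold,
                    "cum_ddg_bind": pt.cumulative_ddg_bind,
                }
            )
    return pd.DataFrame(rows)


def individual_effect_radius(obs: pd.DataFrame) -> float:
    """Largest Euclidean norm √(ΔΔG_fold² + ΔΔG_bind²) over a substitution set.

    This is the radius of the smallest origin-centred circle containing
    every individual substitution, drawn as the dashed reference circle
    on trajectory plots.
    """
    if len(obs) == 0:
        raise ValueError("empty substitution set")
    f = obs["ddg_fold"].to_numpy(float)
    b = obs["ddg_bind"].to_numpy(float)
    return float(np.max(np.hypot(f, b)))


def experiment_weights(
    experiments: Iterable[Experiment],
    temperature_class: TemperatureClass | None = None,
    ancestor_only: bool = False,
) -> dict[SubstitutionKey, int]:
    """Count, per substitution, the number of distinct experiments containing it.

    A substitution appearing in several segments of one experiment counts
    once for that experiment. Filters restrict to a temperature class
    and/or to experiments started from the reference ancestor.
    """
    weights: Counter[SubstitutionKey] = Counter()
    for exp in experiments:
        if temperature_class is not None and exp.temperature_class != temperature_class:
            continue
        if ancestor_only and not exp.ancestor_start:
            continue
        weights.update(exp.all_substitutions())
    return dict(weights)


def weighted_observations(
    weights: dict[SubstitutionKey, int], table: DdgTable
) -> pd.DataFrame:
    """Attach ΔΔG values to weighted substitution keys (columns ddg_fold, ddg_bind, weight)."""
    rows = []
    for key, w in sorted(weights.items()):
        row = table.lookup(key)
        rows.append(
            {
                "site": key.site,
                "aa_from": key.aa_from,
                "aa_to": key.aa_to,
                "ddg_fold": float(row["ddg_fold"]),
                "ddg_bind": float(row["ddg_bind"]),
                "weight": int(w),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Registry I/O (YAML)

def read_experiment_registry(path: str) -> list[Experiment]:
    """Load an experiment registry.

    The registry is a YAML document with a top-level ``experiments`` list;
    each entry has ``id``, ``temperature`` (°C) or ``temperature_class``,
    optional ``ancestor_start`` (default true), ``source_label``, and a
    ``segments`` list of ``{id, parent, substitutions, time}`` records
    where substitutions use compact ``A123T`` notation and the root
    segment has ``parent: null``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_experiment_registry(doc)


def parse_experiment_registry(doc: dict) -> list[Experiment]:
    experiments = []
    for rec in doc.get("experiments", []):
        if "temperature_class" in rec:
            tclass = rec["temperature_class"]
            if tclass not in ("high", "normal", "variable"):
                raise ValueError(f"unknown temperature_class {tclass!r}")
        elif "temperature" in rec:
            tclass = classify_temperature(float(rec["temperature"]))
        else:
            raise ValueError(f"experiment {rec.get('id')!r} lacks temperature information")
        segments = [
            Segment(
                id=str(s["id"]),
                parent=None if s.get("parent") in (None, "") else str(s["parent"]),
                substitutions=[parse_substitution(t) for t in s.get("substitutions", [])],
                time=s.get("time"),
            )
            for s in rec.get("segments", [])
        ]
        experiments.append(
            Experiment(
                id=str(rec["id"]),
                temperature_class=tclass,
                ancestor_start=bool(rec.get("ancestor_start", True)),
                source_label=str(rec.get("source_label", "")),
                segments=segments,
            )
        )
    return experiments


def write_experiment_registry(experiments: Iterable[Experiment], path: str) -> None:
    doc = {
        "experiments": [
            {
                "id": e.id,
                "temperature_class": e.temperature_class,
                "ancestor_start": e.ancestor_start,
                "source_label": e.source_label,
                "segments": [
                    {
                        "id": s.id,
                        "parent": s.parent,
                        "substitutions": [f"{k.aa_from}{k.site}{k.aa_to}" for k in s.substitutions],
                        "time": s.time,
                    }
                    for s in e.segments
                ],
            }
            for e in experiments
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
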