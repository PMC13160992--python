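"""SSR detection in consensus genomes and cross-sample feature-matrix construction.

A simple sequence repeat (SSR, microsatellite) is a tandem array of a 1-6 bp
motif. Because every per-sample consensus genome shares the coordinate frame of
one reference, a marker can be identified across samples by the triple
(locus, motif, full-unit copy count) rather than by coordinate overlap: the
same locus carrying ``(TCA)5`` in one sample and ``(TCA)4`` in another yields
two distinct binary presence/absence features.

The detector reports *maximal perfect runs*: a run is maximal at base
resolution (it cannot be extended left or right by one base while keeping its
period), its motif is the primitive repeat unit as it first appears, and only
full unit copies count. ``N`` bases in a consensus act as wildcards inside a
run; any call whose span covers an ``N`` is flagged so it can be excluded
downstream, mirroring the usual practice of dropping ambiguous consensus
markers before between-sample comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRCall",
    "LocusAnnotation",
    "FeatureKey",
    "FeatureMatrix",
    "GroupLabels",
    "detect_ssrs",
    "classify_calls",
    "assign_loci",
    "build_feature_matrix",
    "primitive_root",
]

#: Minimum number of full unit copies required for detection, per unit length
#: (1=mono .. 6=hexa). These are the smallest counts that occur among
#: published coding-region marker panels of this kind; all are configurable.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

_VALID = set("ACGTN")


def primitive_root(motif: str) -> str:
    """Return the shortest unit whose repetition spells ``motif``.

    ``primitive_root("ATAT") == "AT"``; a primitive motif is its own root.
    """
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return motif[:d]
    return motif  # pragma: no cover - d == n always divides


@dataclass(frozen=True)
class SSRCall:
    """One detected repeat array in one sample.

    Coordinates are 0-based half-open on ``seq_id``. For perfect calls
    ``end - start == len(motif) * repeat_count`` exactly (partial trailing
    units are not counted and not included in the span).
    """

    sample_id: str
    seq_id: str
    start: int
    end: int
    motif: str
    repeat_count: int
    ssr_class: str = "perfect"  # perfect | imperfect | compound
    contains_n: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty span [{self.start},{self.end})")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif length {len(self.motif)} outside 1..6")
        if primitive_root(self.motif) != self.motif:
            raise ValueError(f"motif {self.motif!r} is not primitive")
        if self.ssr_class == "perfect" and self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError("perfect call span must equal motif_length * repeat_count")


@dataclass(frozen=True)
class LocusAnnotation:
    """A gene interval (0-based half-open) with a coding flag."""

    locus_id: str
    seq_id: str
    start: int
    end: int
    is_coding: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.locus_id}: empty interval")


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Cross-sample marker identity: (locus, motif, full-unit copy count)."""

    locus_id: str
    motif: str
    repeat_count: int

    def __str__(self) -> str:
        return f"{self.locus_id}|{self.motif}|{self.repeat_count}"

    @property
    def display(self) -> str:
        """Field display form, e.g. ``LOC115707832 (AAG)5``."""
        return f"{self.locus_id} ({self.motif}){self.repeat_count}"

    @classmethod
    def parse(cls, text: str) -> "FeatureKey":
        locus, motif, count = text.rsplit("|", 2)
        return cls(locus, motif, int(count))


class GroupLabels:
    """Sample -> origin-group mapping with a stable group order."""

    def __init__(self, mapping: Mapping[str, str], groups: Sequence[str] | None = None):
        self.mapping = dict(mapping)
        if groups is None:
            seen: dict[str, None] = {}
            for g in self.mapping.values():
                seen.setdefault(g, None)
            groups = list(seen)
        self.groups = list(groups)
        extra = set(self.mapping.values()) - set(self.groups)
        if extra:
            raise ValueError(f"labels reference groups missing from group order: {sorted(extra)}")

    def __getitem__(self, sample_id: str) -> str:
        return self.mapping[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.mapping[s] for s in sample_ids])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.mapping), "group": list(self.mapping.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroupLabels":
        df = pd.read_csv(path, dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ValueError("labels CSV must have columns sample_id,group")
        return cls(dict(zip(df["sample_id"], df["group"])))


class FeatureMatrix:
    """Binary samples x (locus, motif, count) presence table."""

    def __init__(self, sample_ids: Sequence[str], feature_keys: Sequence[FeatureKey], values):
        self.sample_ids = list(sample_ids)
        self.feature_keys = list(feature_keys)
        self.values = np.asarray(values, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_keys)) != len(self.feature_keys):
            raise ValueError("duplicate feature_keys")
        if self.values.shape != (len(self.sample_ids), len(self.feature_keys)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.feature_keys)})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_keys)

    def restrict(self, keys: Sequence[FeatureKey]) -> "FeatureMatrix":
        """Column subset in the given key order."""
        index = {k: j for j, k in enumerate(self.feature_keys)}
        cols = [index[k] for k in keys]
        return FeatureMatrix(self.sample_ids, list(keys), self.values[:, cols])

    def to_dataframe(self, labels: GroupLabels | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[str(k) for k in self.feature_keys],
        )
        if labels is not None:
            df.insert(0, "group", [labels[s] for s in self.sample_ids])
        return df

    def to_csv(self, path, labels: GroupLabels | None = None) -> None:
        self.to_dataframe(labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> tuple["FeatureMatrix", GroupLabels | None]:
        df = pd.read_csv(path, index_col="sample_id")
        labels = None
        if "group" in df.columns:
            labels = GroupLabels(dict(zip(df.index.astype(str), df.pop("group"))))
        keys = [FeatureKey.parse(c) for c in df.columns]
        return cls(list(df.index.astype(str)), keys, df.to_numpy()), labels


def detect_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] | None = None,
    *,
    sample_id: str = "",
    seq_id: str = "",
) -> list[SSRCall]:
    """Find all maximal perfect SSR runs meeting per-unit-length copy thresholds.

    Returns calls sorted by (start, motif length). ``N`` matches any base when
    extending a run; the motif is read from the first N-free full unit and runs
    without one are dropped. Reports under non-primitive units (``ATAT`` for an
    ``AT`` run) are suppressed, so each underlying run is reported once.
    """
    thr = dict(DEFAULT_MIN_REPEATS)
    if thresholds:
        thr.update(thresholds)
    if any(v < 1 for v in thr.values()):
        raise ValueError("thresholds must be positive")
    seq = sequence.upper()
    if not seq:
        return []
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    L = len(seq)
    calls: list[SSRCall] = []
    for u in range(1, 7):
        if L < u * thr[u]:
            continue
        j = u
        while j < L:
            if seq[j] == seq[j - u] or seq[j] == "N" or seq[j - u] == "N":
                a = j  # first matching offset of this run
                while j < L and (seq[j] == seq[j - u] or seq[j] == "N" or seq[j - u] == "N"):
                    j += 1
                start, stop = a - u, j  # base-maximal periodic span
                count = (stop - start) // u
                if count >= thr[u]:
                    motif = None
                    n_in_span = False
                    for off in range(start, start + count * u, u):
                        unit = seq[off : off + u]
                        if "N" in unit:
                            n_in_span = True
                        elif motif is None:
                            motif = unit
                    if motif is not None and primitive_root(motif) == motif:
                        end = start + count * u
                        calls.append(
                            SSRCall(
                                sample_id=sample_id,
                                seq_id=seq_id,
                                start=start,
                                end=end,
                                motif=motif,
                                repeat_count=count,
                                contains_n=n_in_span or "N" in seq[start:end],
                            )
                        )
            else:
                j += 1
    calls.sort(key=lambda c: (c.start, len(c.motif)))
    return calls


def classify_calls(
    calls: Sequence[SSRCall],
    interrupt_max_bp: int = 4,
    compound_gap_bp: int = 10,
) -> list[SSRCall]:
    """Merge interrupted same-motif runs and mark adjacent different-motif runs.

    Two perfect runs of the same motif separated by at most ``interrupt_max_bp``
    merge into one *imperfect* call whose count is the sum of unit copies.
    After merging, two calls of different motifs separated by at most
    ``compound_gap_bp`` are both marked *compound* (compound takes precedence
    over imperfect). Input must be sorted by (sample_id, seq_id, start).
    """
    if not calls:
        return []
    merged: list[SSRCall] = []
    for call in calls:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.sample_id == call.sample_id
            and prev.seq_id == call.seq_id
            and prev.motif == call.motif
            and prev.ssr_class in ("perfect", "imperfect")
            and call.ssr_class == "perfect"
            and 0 <= call.start - prev.end <= interrupt_max_bp
        ):
            merged[-1] = replace(
                prev,
                end=call.end,
                repeat_count=prev.repeat_count + call.repeat_count,
                ssr_class="imperfect",
                contains_n=prev.contains_n or call.contains_n,
            )
        else:
            merged.append(call)

    out = list(merged)
    for i in range(len(out) - 1):
        a, b = out[i], out[i + 1]
        if (
            a.sample_id == b.sample_id
            and a.seq_id == b.seq_id
            and a.motif != b.motif
            and 0 <= b.start - a.end <= compound_gap_bp
        ):
            out[i] = replace(out[i], ssr_class="compound")
            out[i + 1] = replace(out[i + 1], ssr_class="compound")
    return out


def assign_loci(
    calls: Sequence[SSRCall], annotations: Sequence[LocusAnnotation]
) -> list[tuple[SSRCall, str]]:
    """Assign each call the locus with maximal bp overlap.

    Ties break toward the annotation with the smaller start; calls with no
    overlapping annotation get a binned intergenic pseudo-locus
    ``intergenic:<seq_id>:<floor(start / 10000)>``.
    """
    by_seq: dict[str, list[LocusAnnotation]] = {}
    for ann in annotations:
        by_seq.setdefault(ann.seq_id, []).append(ann)
    for anns in by_seq.values():
        anns.sort(key=lambda a: a.start)

    assigned: list[tuple[SSRCall, str]] = []
    for call in calls:
        best: tuple[int, int, str] | None = None  # (-overlap, ann.start, locus_id)
        for ann in by_seq.get(call.seq_id, ()):
            overlap = min(call.end, ann.end) - max(call.start, ann.start)
            if overlap > 0:
                cand = (-overlap, ann.start, ann.locus_id)
                if best is None or cand < best:
                    best = cand
        if best is None:
            assigned.append((call, f"intergenic:{call.seq_id}:{call.start // 10000}"))
        else:
            assigned.append((call, best[2]))
    return assigned


def build_feature_matrix(
    calls_by_sample: Mapping[str, Sequence[SSRCall]],
    annotations: Sequence[LocusAnnotation],
    labels: GroupLabels,
    *,
    coding_only: bool = False,
    drop_n: bool = True,
    exclude_reference_sample: str | None = None,
) -> FeatureMatrix:
    """Build the binary presence table over (locus, motif, count) keys.

    Columns are the union of keys observed in at least one retained sample;
    the reference sample (if given) contributes neither a row nor a column.
    ``drop_n`` removes calls spanning ambiguous bases before comparison, and
    ``coding_only`` keeps only keys at loci with CDS overlap.
    """
    coding = {a.locus_id for a in annotations if a.is_coding}
    sample_keys: dict[str, set[FeatureKey]] = {}
    for sample_id, calls in calls_by_sample.items():
        if sample_id == exclude_reference_sample:
            continue
        if sample_id not in labels:
            raise ValueError(f"sample {sample_id!r} has no group label")
        keys: set[FeatureKey] = set()
        for call, locus_id in assign_loci(calls, annotations):
            if drop_n and call.contains_n:
                continue
            if coding_only and locus_id not in coding:
                continue
            keys.add(FeatureKey(locus_id, call.motif, call.repeat_count))
        sample_keys[sample_id] = keys

    sample_ids = sorted(sample_keys)
    all_keys = sorted(set().union(*sample_keys.values()) if sample_keys else set())
    values = np.zeros((len(sample_ids), len(all_keys)), dtype=np.int8)
    col = {k: j for j, k in enumerate(all_keys)}
    for i, s in enumerate(sample_ids):
        for k in sample_keys[s]:
            values[i, col[k]] = 1
    return FeatureMatrix(sample_ids, all_keys, values)


def calls_to_tsv(calls: Iterable[SSRCall], path) -> None:
    """Write calls as a TSV (one row per call, 0-based half-open coordinates)."""
    rows = [
        (c.sample_id, c.seq_id, c.start, c.end, c.motif, c.repeat_count, c.ssr_class, int(c.contains_n))
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "seq_id", "start", "end", "motif", "repeat_count", "ssr_class", "contains_n"],
    ).to_csv(path, sep="\t", index=False)
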