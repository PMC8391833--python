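"""mtDNA variant calling, hotspot filtering and motif-based haplogroup calls.

Whole mitochondrial genomes are aligned to a reference in rCRS coordinates
(1-based, 16,569 positions), differences are expressed in standard mtDNA
nomenclature ("16223T", "8281-8289d", "309.1C"), known length-variation
hotspots are excluded, and haplogroups are assigned by scoring diagnostic
motif panels (default panel: the pan-American founder clades A2, B2, C1, D1).

The packaged reference (``data/synthetic_rcrs.fasta``) is a synthetic
stand-in with the rCRS length and coordinate conventions, not the human
sequence; pass your own reference FASTA to work with real genomes.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from pathlib import Path

import edlib
import pandas as pd
from Bio import Align

from .io import SampleMeta, read_fasta

RCRS_LENGTH = 16569

# Length-variation hotspots excluded from all statistics: the control-region
# poly-C stretches and position 16519, plus the two indel windows.
HOTSPOT_SUBSTITUTION_SITES = frozenset(range(16182, 16194)) | {16519}
HOTSPOT_INDEL_WINDOWS = ((303, 315), (515, 522))

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclasses.dataclass(frozen=True)
class MtVariant:
    """One difference from the reference, in rCRS coordinates.

    ``position`` is the first affected reference position; ``end`` the last
    (equal to ``position`` except for multi-base deletions). ``alt`` is the
    alternate base, ``"-"`` for deletions, or the inserted string for
    insertions (anchored after ``position``).
    """

    position: int
    ref: str
    alt: str
    kind: str  # "transition" | "transversion" | "indel"
    end: int = 0

    def __post_init__(self) -> None:
        if self.end == 0:
            object.__setattr__(self, "end", self.position)
        if not (1 <= self.position <= RCRS_LENGTH and self.position <= self.end <= RCRS_LENGTH):
            raise ValueError(f"position {self.position}-{self.end} outside rCRS range")

    @property
    def is_indel(self) -> bool:
        return self.kind == "indel"

    @property
    def is_deletion(self) -> bool:
        return self.kind == "indel" and self.alt == "-"

    @property
    def is_insertion(self) -> bool:
        return self.kind == "indel" and self.alt != "-"

    @property
    def label(self) -> str:
        if self.is_deletion:
            if self.end > self.position:
                return f"{self.position}-{self.end}d"
            return f"{self.position}d"
        if self.is_insertion:
            return f"{self.position}.1{self.alt}"
        return f"{self.position}{self.alt}"


@dataclasses.dataclass
class MtGenome:
    """One typed mitochondrial genome: calls, filtered calls, haplogroup."""

    sample_id: str
    sequence: str
    variants: list[MtVariant]
    filtered_variants: list[MtVariant]
    haplogroup: str = "unassigned"
    match_score: float = 0.0
    meta: SampleMeta | None = None


_LABEL_RE = re.compile(
    r"^(?P<start>\d+)(?:-(?P<end>\d+))?(?:(?P<del>d)|\.(?P<idx>\d+)(?P<ins>[ACGT]+)|(?P<alt>[ACGTN]))$"
)


def parse_variant_label(label: str, reference: str | None = None) -> MtVariant:
    """Parse standard mtDNA nomenclature into an :class:`MtVariant`.

    Accepts substitutions ("16223T"), single- and multi-position deletions
    ("249d", "8281-8289d") and insertions ("309.1C"). When ``reference`` is
    given, substitution ref bases and kinds are derived from it.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparseable variant label {label!r}")
    start = int(m.group("start"))
    if m.group("del"):
        end = int(m.group("end") or start)
        ref = reference[start - 1 : end] if reference else "N" * (end - start + 1)
        return MtVariant(start, ref, "-", "indel", end)
    if m.group("end"):
        raise ValueError(f"range without deletion suffix in {label!r}")
    if m.group("ins"):
        return MtVariant(start, "", m.group("ins"), "indel")
    alt = m.group("alt")
    ref = reference[start - 1] if reference else "N"
    kind = "transition" if (ref, alt) in _TRANSITIONS else "transversion"
    return MtVariant(start, ref, alt, kind)


def load_reference(path: str | Path | None = None) -> str:
    """Load the reference genome (packaged synthetic stand-in by default)."""
    if path is None:
        ref = resources.files("unipargen").joinpath("data/synthetic_rcrs.fasta")
        with resources.as_file(ref) as p:
            return read_fasta(p)[0][1]
    return read_fasta(path)[0][1]


def _classify_substitution(ref: str, alt: str) -> str:
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


# affine-gap aligner used to renormalize indel clusters on short windows;
# with a gap-open cost, equal-length indels coalesce into one run instead of
# scattering across coincidentally matching bases
_AFFINE = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-1,
)


def _window_variants(ref_w: str, q_w: str, ref_offset: int) -> list[MtVariant]:
    """Variants of a short window re-aligned with affine gap costs.

    ``ref_offset`` is the 0-based reference position of ``ref_w[0]``.
    """
    aln = _AFFINE.align(ref_w, q_w)[0]
    t_blocks, q_blocks = aln.aligned
    out: list[MtVariant] = []
    pt, pq = 0, 0

    def flush_gap(t_to: int, q_to: int) -> None:
        nonlocal pt, pq
        if t_to > pt:
            out.append(
                MtVariant(
                    ref_offset + pt + 1, ref_w[pt:t_to], "-", "indel", ref_offset + t_to
                )
            )
        if q_to > pq:
            anchor = max(ref_offset + pt, 1)
            out.append(MtVariant(anchor, "", q_w[pq:q_to], "indel"))
        pt, pq = t_to, q_to

    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        flush_gap(ts, qs)
        for i in range(te - ts):
            rb, qb = ref_w[ts + i], q_w[qs + i]
            if rb != qb:
                out.append(
                    MtVariant(ref_offset + ts + i + 1, rb, qb, _classify_substitution(rb, qb))
                )
        pt, pq = te, qe
    flush_gap(len(ref_w), len(q_w))
    return out


def _normalize_variants(
    raw: list[tuple[MtVariant, int, int]], reference: str, sequence: str
) -> list[MtVariant]:
    """Re-align clusters of nearby variants containing indels with affine
    gap costs so contiguous indels merge into single records."""
    gap, pad = 15, 7
    out: list[MtVariant] = []
    i = 0
    while i < len(raw):
        j = i
        while j + 1 < len(raw) and raw[j + 1][0].position - raw[j][0].end <= gap:
            j += 1
        cluster = raw[i : j + 1]
        has_indel = any(v.is_indel for v, _, _ in cluster)
        if len(cluster) >= 2 and has_indel:
            rs = max(cluster[0][0].position - 1 - pad, 0)
            re_ = min(cluster[-1][0].end + pad, len(reference))
            qs = cluster[0][1] - (cluster[0][0].position - 1 - rs)
            qe = cluster[-1][2] + (re_ - cluster[-1][0].end)
            qs, qe = max(qs, 0), min(qe, len(sequence))
            out.extend(_window_variants(reference[rs:re_], sequence[qs:qe], rs))
        else:
            out.extend(v for v, _, _ in cluster)
        i = j + 1
    return out


def call_variants(sequence: str, reference: str, min_identity: float = 0.95) -> list[MtVariant]:
    """Align a genome to the reference and report differences as variants.

    The global alignment path comes from edlib; clusters of nearby indels
    are re-aligned with affine gap costs so that contiguous deleted
    reference positions merge into one deletion record and contiguous
    inserted bases into one insertion record. Applying the returned
    variants to the reference reconstructs the input sequence exactly.
    """
    if not sequence or not reference:
        raise ValueError("empty sequence")
    sequence = sequence.upper().replace("-", "")
    if abs(len(sequence) - len(reference)) > 50:
        raise ValueError(
            f"sequence length {len(sequence)} too far from reference {len(reference)}"
        )
    aln = edlib.align(sequence, reference, mode="NW", task="path")
    if aln["editDistance"] / len(reference) > 1.0 - min_identity:
        raise ValueError(
            f"alignment identity below {min_identity:.0%}: not a matching mtDNA genome"
        )
    raw: list[tuple[MtVariant, int, int]] = []  # (variant, qstart, qend)
    tpos = 0  # consumed reference bases
    qpos = 0
    for n_str, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"]):
        n = int(n_str)
        if op in ("=", "M"):
            tpos += n
            qpos += n
        elif op == "X":
            for i in range(n):
                ref_b = reference[tpos + i]
                alt_b = sequence[qpos + i]
                raw.append(
                    (
                        MtVariant(
                            tpos + i + 1, ref_b, alt_b, _classify_substitution(ref_b, alt_b)
                        ),
                        qpos + i,
                        qpos + i + 1,
                    )
                )
            tpos += n
            qpos += n
        elif op == "D":  # reference bases absent from the query: deletion
            raw.append(
                (
                    MtVariant(tpos + 1, reference[tpos : tpos + n], "-", "indel", tpos + n),
                    qpos,
                    qpos,
                )
            )
            tpos += n
        elif op == "I":  # extra query bases: insertion after reference position tpos
            anchor = max(tpos, 1)
            raw.append(
                (MtVariant(anchor, "", sequence[qpos : qpos + n], "indel"), qpos, qpos + n)
            )
            qpos += n
    return _normalize_variants(raw, reference, sequence)


def apply_variants(reference: str, variants: list[MtVariant]) -> str:
    """Apply non-overlapping variants (reference coordinates) to the reference."""
    subs: dict[int, str] = {}
    deleted: set[int] = set()
    inserts: dict[int, str] = {}
    for v in variants:
        if v.is_deletion:
            deleted.update(range(v.position, v.end + 1))
        elif v.is_insertion:
            inserts[v.position] = inserts.get(v.position, "") + v.alt
        else:
            subs[v.position] = v.alt
    out: list[str] = []
    for pos in range(1, len(reference) + 1):
        if pos not in deleted:
            out.append(subs.get(pos, reference[pos - 1]))
        if pos in inserts:
            out.append(inserts[pos])
    return "".join(out)


def hotspot_filter(variants: list[MtVariant]) -> list[MtVariant]:
    """Drop hotspot substitutions (16182-16193, 16519) and indels touching
    the 303-315 / 515-522 windows; everything else is retained in order."""
    kept = []
    for v in variants:
        if v.is_indel:
            span = (v.position, v.end)
            if any(span[0] <= hi and span[1] >= lo for lo, hi in HOTSPOT_INDEL_WINDOWS):
                continue
        elif v.position in HOTSPOT_SUBSTITUTION_SITES:
            continue
        kept.append(v)
    return kept


@dataclasses.dataclass(frozen=True)
class MotifPanel:
    """Diagnostic motifs per haplogroup label.

    A genome scores, for each label, the fraction of that label's motif
    sites present among its (hotspot-filtered) variants; the best label wins
    if its score reaches ``min_match_fraction``.
    """

    motifs: dict[str, tuple[MtVariant, ...]]
    min_match_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("empty motif panel")
        if not 0 < self.min_match_fraction <= 1:
            raise ValueError("min_match_fraction must be in (0, 1]")

    @property
    def labels(self) -> list[str]:
        return sorted(self.motifs)


def read_motif_panel(
    path: str | Path, reference: str | None = None, min_match_fraction: float = 0.8
) -> MotifPanel:
    """Read a motif panel TSV with columns ``haplogroup`` and ``variant``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    motifs: dict[str, list[MtVariant]] = {}
    for row in df.itertuples(index=False):
        motifs.setdefault(row.haplogroup, []).append(
            parse_variant_label(row.variant, reference)
        )
    return MotifPanel({k: tuple(v) for k, v in motifs.items()}, min_match_fraction)


def load_default_motifs(reference: str | None = None, min_match_fraction: float = 0.8) -> MotifPanel:
    """The packaged A2/B2/C1/D1 panel (alt states match the packaged
    synthetic reference; supply your own panel for real data)."""
    res = resources.files("unipargen").joinpath("data/default_motifs.tsv")
    with resources.as_file(res) as p:
        return read_motif_panel(p, reference, min_match_fraction)


def _motif_site_matched(site: MtVariant, variants: list[MtVariant]) -> bool:
    for v in variants:
        if site.is_deletion:
            if v.is_deletion and v.position <= site.end and v.end >= site.position:
                return True
        elif site.is_insertion:
            if v.is_insertion and v.position == site.position and v.alt == site.alt:
                return True
        elif not v.is_indel and v.position == site.position and v.alt == site.alt:
            return True
    return False


def assign_haplogroup(
    filtered_variants: list[MtVariant], panel: MotifPanel
) -> tuple[str, float]:
    """Best-scoring haplogroup label, or ``"unassigned"`` below threshold.

    Ties go to the label with the larger motif, then lexicographically.
    """
    best: tuple[float, int, str] | None = None
    best_label = "unassigned"
    for label in panel.labels:
        sites = panel.motifs[label]
        score = sum(_motif_site_matched(s, filtered_variants) for s in sites) / len(sites)
        key = (score, len(sites), _LexDesc(label))
        if best is None or key > best:
            best = key
            best_label = label
    assert best is not None
    score = best[0]
    if score < panel.min_match_fraction:
        return "unassigned", score
    return best_label, score


class _LexDesc(str):
    """String ordering reversed, so max() prefers the lexicographically
    smaller label on full ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def type_genomes(
    records: list[tuple[str, str]],
    reference: str,
    panel: MotifPanel,
    meta: dict[str, SampleMeta] | None = None,
) -> list[MtGenome]:
    """Call, filter and haplogroup-type a batch of genomes."""
    out = []
    for sid, seq in records:
        variants = call_variants(seq, reference)
        filtered = hotspot_filter(variants)
        label, score = assign_haplogroup(filtered, panel)
        out.append(
            MtGenome(
                sample_id=sid,
                sequence=seq.upper(),
                variants=variants,
                filtered_variants=filtered,
                haplogroup=label,
                match_score=score,
                meta=None if meta is None else meta.get(sid),
            )
        )
    return out


def haplogroup_frequency_table(
    genomes: list[MtGenome], meta: dict[str, SampleMeta]
) -> pd.DataFrame:
    """Population x haplogroup relative-frequency matrix (rows sum to 1)."""
    rows: dict[str, dict[str, int]] = {}
    for g in genomes:
        m = g.meta or meta.get(g.sample_id)
        if m is None:
            raise ValueError(f"no metadata for sample {g.sample_id!r}")
        rows.setdefault(m.population, {}).setdefault(g.haplogroup, 0)
        rows[m.population][g.haplogroup] += 1
    df = pd.DataFrame(rows).T.fillna(0.0).sort_index()
    df = df[sorted(df.columns)]
    return df.div(df.sum(axis=1), axis=0)


def calls_table(genomes: list[MtGenome]) -> pd.DataFrame:
    """Per-sample TSV-ready table of haplogroup calls and variant strings."""
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in genomes],
            "haplogroup": [g.haplogroup for g in genomes],
            "score": [g.match_score for g in genomes],
            "variants": [" ".join(v.label for v in g.filtered_variants) for g in genomes],
        }
    )
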