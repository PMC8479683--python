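"""Text-format I/O: labelled FASTA, cluster membership files, TSV tables, config.

FASTA headers carry labels as ``key=value`` pairs after the id, e.g.::

    >g1 species=Escherichia coli family=f7

Values may contain spaces; a value runs until the next ``key=`` token.
Recognised keys: species, genus, family, fragment.  A sidecar TSV with the
same labels can be written alongside.

The membership file is a documented CD-HIT ``.clstr``-style dialect::

    >Cluster 0
    0\t16111nt, >repid... *
    1\t7122nt, >memberid... at 100.00%

The representative line ends in ``*``; member lines record the admission
identity.  Round-trips are lossless for membership, lengths and identities.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

from .align import AlignmentStats
from .cluster import Catalog, Cluster, ClusteringParams, leaf
from .synth import LabeledSequence

_KV_KEYS = ("species", "genus", "family", "fragment")
_KV_RE = re.compile(r"\b(" + "|".join(_KV_KEYS) + r")=")


def _parse_header_labels(description: str) -> dict[str, str]:
    """Parse key=value pairs where values may contain spaces."""
    hits = list(_KV_RE.finditer(description))
    out: dict[str, str] = {}
    for i, m in enumerate(hits):
        end = hits[i + 1].start() if i + 1 < len(hits) else len(description)
        out[m.group(1)] = description[m.end():end].strip()
    return out


def read_fasta(path: str | Path) -> list[LabeledSequence]:
    """Read FASTA with optional key=value labels in headers."""
    seqs: list[LabeledSequence] = []
    seen: set[str] = set()
    sid = None
    labels: dict[str, str] = {}
    chunks: list[str] = []
    line_no_of_id = 0

    def flush(line_no):
        if sid is None:
            return
        bases = "".join(chunks)
        if not bases:
            raise ValueError(f"{path}: record {sid!r} (line {line_no_of_id}) has no sequence")
        seqs.append(LabeledSequence(
            id=sid, bases=bases,
            species=labels.get("species"),
            genus=labels.get("genus"),
            family_id=labels.get("family"),
            is_fragment=labels.get("fragment", "").lower() in ("1", "true")))

    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush(ln)
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}: empty header at line {ln}")
                parts = header.split(None, 1)
                sid = parts[0]
                if sid in seen:
                    raise ValueError(f"{path}: duplicate id {sid!r} at line {ln}")
                seen.add(sid)
                labels = _parse_header_labels(parts[1]) if len(parts) > 1 else {}
                chunks = []
                line_no_of_id = ln
            else:
                if sid is None:
                    raise ValueError(f"{path}: sequence before header at line {ln}")
                if not re.fullmatch(r"[ACGTNacgtn]+", line):
                    raise ValueError(f"{path}: malformed sequence at line {ln}")
                chunks.append(line.upper())
        flush(0)
    return seqs


def write_fasta(seqs: list[LabeledSequence], path: str | Path,
                width: int = 60, sidecar_tsv: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            parts = [s.id]
            if s.species is not None:
                parts.append(f"species={s.species}")
            if s.genus is not None and (s.species is None
                                        or s.genus != s.species.split()[0]):
                parts.append(f"genus={s.genus}")
            if s.family_id is not None:
                parts.append(f"family={s.family_id}")
            if s.is_fragment:
                parts.append("fragment=1")
            fh.write(">" + " ".join(parts) + "\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i:i + width] + "\n")
    if sidecar_tsv is not None:
        with open(sidecar_tsv, "w") as fh:
            fh.write("id\tspecies\tgenus\tfamily_id\tis_fragment\n")
            for s in seqs:
                fh.write("\t".join([
                    s.id, s.species or "", s.genus or "", s.family_id or "",
                    "1" if s.is_fragment else "0"]) + "\n")


_CLSTR_MEMBER_RE = re.compile(
    r"^(\d+)\t(\d+)nt, >(.+?)\.\.\. (?:\*|at (\d+\.\d+)%)$")


def write_clstr(catalog: Catalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ci, cl in enumerate(catalog.clusters):
            fh.write(f">Cluster {ci}\n")
            for mi, (mid, stats) in enumerate(cl.members):
                length = len(catalog.sequence_index[mid]) \
                    if mid in catalog.sequence_index else stats.query_length
                if mid == cl.representative_id:
                    fh.write(f"{mi}\t{length}nt, >{mid}... *\n")
                else:
                    fh.write(f"{mi}\t{length}nt, >{mid}... at "
                             f"{100.0 * stats.identity:.2f}%\n")


def read_clstr(path: str | Path,
               sequences: dict[str, LabeledSequence] | None = None) -> Catalog:
    """Parse the membership dialect back into a Catalog.

    Admission stats are reconstructed minimally (identity and lengths only);
    a missing representative (``*``) line is an error.
    """
    clusters: list[Cluster] = []
    pending: list[tuple[str, int, float | None]] = []

    def flush(block_line):
        if not pending and not clusters and block_line == 0:
            return
        rep = [p for p in pending if p[2] is None]
        if len(rep) != 1:
            raise ValueError(f"{path}: cluster block before line {block_line} "
                             f"has {len(rep)} representative lines (need 1)")
        rep_id, rep_len, _ = rep[0]
        members = []
        for mid, length, ident in pending:
            identity = 1.0 if ident is None else ident / 100.0
            members.append((mid, AlignmentStats(
                identity=identity, query_coverage=1.0,
                target_coverage=length / rep_len,
                target_interval=(0, length),
                matches=round(identity * length), alignment_columns=length,
                score=0, query_length=length, target_length=rep_len)))
        clusters.append(Cluster(rep_id, members))

    started = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                if started:
                    flush(ln)
                pending = []
                started = True
                continue
            m = _CLSTR_MEMBER_RE.match(line)
            if m is None:
                raise ValueError(f"{path}: unrecognised line {ln}: {line!r}")
            if not started:
                raise ValueError(f"{path}: member before cluster header, line {ln}")
            _, length, mid, ident = m.groups()
            pending.append((mid, int(length),
                            None if ident is None else float(ident)))
    if started:
        flush(-1)
    index = sequences or {}
    return Catalog(clusters, dict(index), leaf(ClusteringParams()))


@dataclasses.dataclass
class RunConfig:
    """Resolved run configuration, written next to every CLI output."""

    params: ClusteringParams = dataclasses.field(default_factory=ClusteringParams)
    seeds: dict[str, int] = dataclasses.field(default_factory=dict)
    paths: dict[str, str] = dataclasses.field(default_factory=dict)
    identity_definition: str = "alignment_columns"
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        params = ClusteringParams(**d.pop("params", {}))
        return cls(params=params, **d)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
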