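"""Domain types and I/O for weighted bipartite interaction networks.

A weighted network records counts ``B_ijk`` of interaction events (for
host-parasitoid systems: successful parasitism events) between a resource
species *i* and a consumer species *j* at a field site *k*.  Networks sampled
at several field sites of one habitat type form a :class:`NetworkGroup`, which
shares a single :class:`SpeciesRegistry` and carries the habitat metadata used
to situate groups along axes of habitat modification (habitat complexity and
consumer-resource ratio).

Two plain-text formats are supported:

* **edgelist** — a delimited file with header ``site,host,parasitoid,count``
  (tab or comma, autodetected) plus an optional YAML/JSON metadata sidecar.
* **matrix** — a directory with a ``group.yaml`` manifest and one count matrix
  per site (hosts as rows, parasitoids as columns, identifier headers).

Zero counts are stored only as explicit "observed-possible-but-zero" markers
(e.g. a link known to be forbidden); they never enter the evaluation support,
which contains exactly the cells with strictly positive counts.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "Link",
    "Cell",
    "NetworkError",
    "ParseError",
    "ValidationError",
    "SpeciesRegistry",
    "WeightedNetwork",
    "NetworkGroup",
    "SupportMask",
    "read_group",
    "write_group",
    "aggregate_counts",
    "support_mask",
    "consumer_resource_ratio",
]

#: (host_id, parasitoid_id)
Link = tuple[str, str]
#: (host_id, parasitoid_id, site_id)
Cell = tuple[str, str, str]

HABITAT_COMPLEXITY_LABELS = ("forested", "open", "unknown")
CONSUMER_RESOURCE_LABELS = ("low", "high", "unknown")

EDGELIST_HEADER = ("site", "host", "parasitoid", "count")


class NetworkError(Exception):
    """Base class for network data errors."""


class ParseError(NetworkError):
    """A file could not be parsed as network data."""


class ValidationError(NetworkError):
    """Network data violates a structural invariant."""


def _check_count(value: object, where: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int,)):
        # numpy integers pass through the int() path in the parsers
        raise ValidationError(f"non-integer count {value!r} {where}")
    if value < 0:
        raise ValidationError(f"negative count {value} {where}")
    return int(value)


@dataclass(frozen=True)
class SpeciesRegistry:
    """Ordered species identifiers for the two guilds of a bipartite system."""

    hosts: tuple[str, ...]
    parasitoids: tuple[str, ...]

    def __post_init__(self) -> None:
        for guild, ids in (("host", self.hosts), ("parasitoid", self.parasitoids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {guild} identifiers in registry")
        if not self.hosts or not self.parasitoids:
            raise ValidationError("registry needs at least one species per guild")

    @classmethod
    def from_lists(cls, hosts: Iterable[str], parasitoids: Iterable[str]) -> "SpeciesRegistry":
        return cls(tuple(hosts), tuple(parasitoids))


@dataclass
class WeightedNetwork:
    """Interaction counts recorded at one field site.

    ``counts`` maps ``(host_id, parasitoid_id)`` to a nonnegative integer
    number of recorded interaction events.  Entries with count 0 are explicit
    markers (a link recorded as possible but unobserved, e.g. forbidden) and
    are excluded from the positive support.
    """

    site_id: str
    counts: dict[Link, int]

    def __post_init__(self) -> None:
        clean: dict[Link, int] = {}
        for link, c in self.counts.items():
            clean[(str(link[0]), str(link[1]))] = _check_count(
                int(c) if not isinstance(c, bool) else c,
                f"for link {link} at site {self.site_id!r}",
            )
        self.counts = clean

    @property
    def total_counts(self) -> int:
        return sum(self.counts.values())

    def positive_links(self) -> set[Link]:
        return {link for link, c in self.counts.items() if c > 0}

    def species(self) -> tuple[set[str], set[str]]:
        hosts = {h for (h, _p) in self.counts}
        pars = {p for (_h, p) in self.counts}
        return hosts, pars


@dataclass
class NetworkGroup:
    """An ordered collection of site networks from one habitat type."""

    group_id: str
    registry: SpeciesRegistry
    networks: list[WeightedNetwork]
    habitat_complexity: str = "unknown"
    consumer_resource_label: str = "unknown"
    totals_for_ratio: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValidationError(f"group {self.group_id!r} has no networks")
        if self.habitat_complexity not in HABITAT_COMPLEXITY_LABELS:
            raise ValidationError(
                f"habitat_complexity must be one of {HABITAT_COMPLEXITY_LABELS}"
            )
        if self.consumer_resource_label not in CONSUMER_RESOURCE_LABELS:
            raise ValidationError(
                f"consumer_resource_label must be one of {CONSUMER_RESOURCE_LABELS}"
            )
        site_ids = [n.site_id for n in self.networks]
        if len(set(site_ids)) != len(site_ids):
            raise ValidationError(f"duplicate site_ids in group {self.group_id!r}")
        known_h, known_p = set(self.registry.hosts), set(self.registry.parasitoids)
        for net in self.networks:
            hs, ps = net.species()
            if not hs <= known_h:
                raise ValidationError(
                    f"hosts {sorted(hs - known_h)} at site {net.site_id!r} missing from registry"
                )
            if not ps <= known_p:
                raise ValidationError(
                    f"parasitoids {sorted(ps - known_p)} at site {net.site_id!r} "
                    "missing from registry"
                )
        if self.totals_for_ratio is not None:
            tp, th = self.totals_for_ratio
            self.totals_for_ratio = (int(tp), int(th))

    @property
    def site_ids(self) -> list[str]:
        return [n.site_id for n in self.networks]

    @property
    def total_counts(self) -> int:
        return sum(n.total_counts for n in self.networks)

    def network(self, site_id: str) -> WeightedNetwork:
        for n in self.networks:
            if n.site_id == site_id:
                return n
        raise KeyError(site_id)

    def positive_links(self) -> set[Link]:
        out: set[Link] = set()
        for n in self.networks:
            out |= n.positive_links()
        return out

    def counts_on(self, cells: Iterable[Cell]) -> dict[Cell, int]:
        """Counts restricted to the given (host, parasitoid, site) cells."""
        by_site = {n.site_id: n for n in self.networks}
        return {
            (h, p, k): by_site[k].counts.get((h, p), 0) for (h, p, k) in cells
        }


@dataclass(frozen=True)
class SupportMask:
    """Cells ``(host, parasitoid, site)`` with ``a_ijk = 1``.

    The support is the set of cells with strictly positive recorded counts;
    model probability vectors are defined over it.
    """

    cells: frozenset[Cell]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValidationError("support mask has no evaluable cells")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.sorted_cells())

    def sorted_cells(self) -> list[Cell]:
        return sorted(self.cells)

    @property
    def links(self) -> set[Link]:
        return {(h, p) for (h, p, _k) in self.cells}

    @property
    def sites(self) -> set[str]:
        return {k for (_h, _p, k) in self.cells}

    def cells_at_site(self, site_id: str) -> list[Cell]:
        return sorted(c for c in self.cells if c[2] == site_id)

    def hosts_of_column(self, parasitoid_id: str) -> list[str]:
        return sorted({h for (h, p, _k) in self.cells if p == parasitoid_id})

    @property
    def parasitoids(self) -> list[str]:
        return sorted({p for (_h, p, _k) in self.cells})


# ---------------------------------------------------------------------------
# descriptive operations
# ---------------------------------------------------------------------------

def aggregate_counts(group: NetworkGroup) -> dict[Link, int]:
    """Per-link count sums across all sites, ``Σ_k B_ijk``.

    Links recorded only as zero markers appear with sum 0; use
    ``{l: s for l, s in ... if s > 0}`` for the positive-link set.
    """
    sums: dict[Link, int] = {}
    for net in group.networks:
        for link, c in net.counts.items():
            sums[link] = sums.get(link, 0) + c
    return sums


def support_mask(group: NetworkGroup) -> SupportMask:
    """The group's evaluation support: one cell per strictly positive count."""
    cells = frozenset(
        (h, p, net.site_id)
        for net in group.networks
        for (h, p), c in net.counts.items()
        if c > 0
    )
    if not cells:
        raise ValidationError(f"group {group.group_id!r} has no evaluable cells")
    return SupportMask(cells)


def consumer_resource_ratio(total_parasitism: int, total_hosts: int) -> float:
    """Total successful parasitism events over total hosts collected.

    A proxy for how easily consumers locate resources in a habitat type.
    """
    if total_hosts <= 0:
        raise ValidationError("total_hosts must be > 0")
    if total_parasitism < 0:
        raise ValidationError("total_parasitism must be >= 0")
    return total_parasitism / total_hosts


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def _metadata_dict(group: NetworkGroup) -> dict:
    return {
        "group_id": group.group_id,
        "habitat_complexity": group.habitat_complexity,
        "consumer_resource_label": group.consumer_resource_label,
        "totals_for_ratio": list(group.totals_for_ratio)
        if group.totals_for_ratio is not None
        else None,
        "hosts": list(group.registry.hosts),
        "parasitoids": list(group.registry.parasitoids),
        # sites with no recorded entries would otherwise vanish on round-trip
        "site_ids": [n.site_id for n in group.networks],
    }


def _group_from_records(
    records: list[tuple[str, str, str, int]],
    meta: Optional[dict],
    default_group_id: str,
) -> NetworkGroup:
    meta = meta or {}
    if meta.get("hosts") and meta.get("parasitoids"):
        registry = SpeciesRegistry.from_lists(meta["hosts"], meta["parasitoids"])
    else:
        hosts: list[str] = []
        pars: list[str] = []
        for (_s, h, p, _c) in records:
            if h not in hosts:
                hosts.append(h)
            if p not in pars:
                pars.append(p)
        registry = SpeciesRegistry.from_lists(hosts, pars)
    site_order: list[str] = [str(s) for s in meta.get("site_ids", [])]
    per_site: dict[str, dict[Link, int]] = {s: {} for s in site_order}
    for (s, h, p, c) in records:
        if s not in per_site:
            per_site[s] = {}
            site_order.append(s)
        if (h, p) in per_site[s]:
            raise ValidationError(f"duplicate record for ({h}, {p}) at site {s!r}")
        per_site[s][(h, p)] = c
    networks = [WeightedNetwork(s, per_site[s]) for s in site_order]
    totals = meta.get("totals_for_ratio")
    return NetworkGroup(
        group_id=meta.get("group_id", default_group_id),
        registry=registry,
        networks=networks,
        habitat_complexity=meta.get("habitat_complexity", "unknown"),
        consumer_resource_label=meta.get("consumer_resource_label", "unknown"),
        totals_for_ratio=tuple(totals) if totals is not None else None,
    )


def _parse_count(raw: str, lineno: int, path: Path) -> int:
    raw = raw.strip()
    try:
        value = int(raw)
    except ValueError:
        raise ValidationError(
            f"{path}:{lineno}: non-integer count {raw!r}"
        ) from None
    if value < 0:
        raise ValidationError(f"{path}:{lineno}: negative count {value}")
    return value


def _read_edgelist(path: Path) -> NetworkGroup:
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: no interaction records")
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delimiter)
    rows = list(reader)
    header = tuple(c.strip().lower() for c in rows[0])
    if header != EDGELIST_HEADER:
        raise ParseError(
            f"{path}:1: expected header {','.join(EDGELIST_HEADER)}, got {rows[0]!r}"
        )
    if len(rows) == 1:
        raise ParseError(f"{path}: no interaction records")
    records: list[tuple[str, str, str, int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
        site, host, par, raw = (c.strip() for c in row)
        if not site or not host or not par:
            raise ParseError(f"{path}:{lineno}: empty identifier field")
        records.append((site, host, par, _parse_count(raw, lineno, path)))
    meta = None
    mpath = _meta_path(path)
    if mpath.exists():
        meta = yaml.safe_load(mpath.read_text(encoding="utf-8"))
    return _group_from_records(records, meta, default_group_id=path.stem)


def _write_edgelist(group: NetworkGroup, path: Path) -> None:
    delimiter = "\t" if path.suffix == ".tsv" else ","
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(EDGELIST_HEADER)
        for net in group.networks:
            for (h, p) in sorted(net.counts):
                writer.writerow([net.site_id, h, p, net.counts[(h, p)]])
    _meta_path(path).write_text(
        yaml.safe_dump(_metadata_dict(group), sort_keys=False), encoding="utf-8"
    )


def _read_matrix_dir(path: Path) -> NetworkGroup:
    manifest_path = path / "group.yaml"
    if not manifest_path.exists():
        raise ParseError(f"{manifest_path}: manifest not found")
    meta = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    records: list[tuple[str, str, str, int]] = []
    sites = meta.get("sites") or []
    if not sites:
        raise ParseError(f"{manifest_path}: no sites listed")
    meta = dict(meta)
    meta["site_ids"] = [str(entry["site_id"]) for entry in sites]
    for entry in sites:
        site_id = str(entry["site_id"])
        mfile = path / entry["file"]
        lines = [
            ln for ln in mfile.read_text(encoding="utf-8").splitlines() if ln.strip()
        ]
        if not lines:
            # a site with no recorded entries at all
            continue
        header = lines[0].split("\t")
        if header[0] != "host":
            raise ParseError(f"{mfile}:1: first column header must be 'host'")
        pars = header[1:]
        for lineno, ln in enumerate(lines[1:], start=2):
            fields = ln.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{mfile}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            host = fields[0]
            for par, raw in zip(pars, fields[1:]):
                if raw.strip() == ".":
                    continue  # not recorded at this site
                records.append((site_id, host, par, _parse_count(raw, lineno, mfile)))
    if not records:
        raise ParseError(f"{path}: no interaction records")
    return _group_from_records(records, meta, default_group_id=path.name)


def _write_matrix_dir(group: NetworkGroup, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = _metadata_dict(group)
    meta["sites"] = [
        {"site_id": n.site_id, "file": f"site_{i:03d}.tsv"}
        for i, n in enumerate(group.networks)
    ]
    (path / "group.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False), encoding="utf-8"
    )
    for i, net in enumerate(group.networks):
        hosts = [h for h in group.registry.hosts if any(link[0] == h for link in net.counts)]
        pars = [p for p in group.registry.parasitoids if any(link[1] == p for link in net.counts)]
        lines = ["\t".join(["host"] + pars)]
        for h in hosts:
            row = [h]
            for p in pars:
                c = net.counts.get((h, p))
                row.append("." if c is None else str(c))
            lines.append("\t".join(row))
        (path / f"site_{i:03d}.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_group(path: str | Path, format: str = "edgelist") -> NetworkGroup:
    """Read a validated :class:`NetworkGroup` from disk.

    ``format`` is ``"edgelist"`` (single delimited file plus optional
    ``<stem>.meta.yaml`` sidecar) or ``"matrix"`` (directory with a
    ``group.yaml`` manifest and one count matrix per site).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "matrix":
        return _read_matrix_dir(path)
    raise ValueError(f"unknown format {format!r}")


def write_group(group: NetworkGroup, path: str | Path, format: str = "edgelist") -> None:
    """Write a group to disk; ``read_group(write_group(g)) == g`` for both formats."""
    path = Path(path)
    if format == "edgelist":
        _write_edgelist(group, path)
    elif format == "matrix":
        _write_matrix_dir(group, path)
    else:
        raise ValueError(f"unknown format {format!r}")
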