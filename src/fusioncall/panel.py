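"""Probe-panel manifests for multiplexed gene fusion assays.

A manifest declares every probe set in one hybridization panel: the
fusion-breakpoint probes, the housekeeping probes used to judge RNA
adequacy, and the spiked positive/negative assay controls, together with
the association of each fusion with the leukemia lineages in which it is
typically found (e.g. ``BCR::ABL1`` in B-ALL or CML).

The positive controls form a titration ladder: they are listed in
descending order of spiked concentration, and downstream assay QC relies
on that ordering.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class ManifestError(ValueError):
    """A manifest file or object violates its structural invariants."""


class ProbeKind(enum.Enum):
    FUSION = "fusion"
    HOUSEKEEPING = "housekeeping"
    POS_CONTROL = "pos_control"
    NEG_CONTROL = "neg_control"


class Tube(enum.Enum):
    """Multiplexed reaction tube of a two-tube hematologic panel."""

    HEME1 = "HEME1"
    HEME2 = "HEME2"


class Lineage(enum.Enum):
    """Leukemia lineage labels used for immunophenotype concordance.

    Non-leukemia entities covered by some panel fusions (lymphoma,
    histiocytosis, ALCL, ...) collapse onto ``OTHER``.
    """

    B_ALL = "B-ALL"
    T_ALL = "T-ALL"
    AML = "AML"
    CML = "CML"
    MPAL = "MPAL"
    OTHER = "other"


@dataclass(frozen=True)
class ProbeSet:
    """One probe set: a pair of hybridization probes counted as a unit.

    ``fusion_id`` names the fusion a breakpoint probe detects (several
    probe sets may target distinct breakpoints of the same fusion) and is
    present exactly for probes of kind ``FUSION``.  ``tube`` is ``None``
    for probes present in every tube (controls, housekeeping).
    """

    probe_id: str
    kind: ProbeKind
    fusion_id: str | None = None
    tube: Tube | None = None
    lineages: frozenset[Lineage] = frozenset()

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ManifestError("probe_id must be non-empty")
        if (self.kind is ProbeKind.FUSION) != (self.fusion_id is not None):
            raise ManifestError(
                f"probe {self.probe_id!r}: fusion_id is required for FUSION "
                "probes and forbidden for other kinds"
            )


@dataclass
class PanelManifest:
    """The probe universe of one panel plus fusion-to-lineage mapping."""

    name: str
    probes: list[ProbeSet]

    def __post_init__(self) -> None:
        index: dict[str, ProbeSet] = {}
        for probe in self.probes:
            if probe.probe_id in index:
                raise ManifestError(f"duplicate probe_id {probe.probe_id!r}")
            index[probe.probe_id] = probe
        self._index = index

    # -- lookups ---------------------------------------------------------
    def probe(self, probe_id: str) -> ProbeSet:
        return self._index[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._index

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def fusion_probes(self) -> list[ProbeSet]:
        return [p for p in self.probes if p.kind is ProbeKind.FUSION]

    @property
    def fusion_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.fusion_probes:
            seen.setdefault(p.fusion_id, None)  # type: ignore[arg-type]
        return list(seen)

    @property
    def housekeeping_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes if p.kind is ProbeKind.HOUSEKEEPING]

    @property
    def pos_control_ids(self) -> list[str]:
        """Positive-control probe ids in ladder order (highest spike first)."""
        return [p.probe_id for p in self.probes if p.kind is ProbeKind.POS_CONTROL]

    @property
    def neg_control_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes if p.kind is ProbeKind.NEG_CONTROL]

    @property
    def lineage_map(self) -> dict[str, frozenset[Lineage]]:
        out: dict[str, frozenset[Lineage]] = {}
        for p in self.fusion_probes:
            fid = p.fusion_id
            assert fid is not None
            out[fid] = out.get(fid, frozenset()) | p.lineages
        return out

    def probes_for_fusion(self, fusion_id: str) -> list[ProbeSet]:
        return [p for p in self.fusion_probes if p.fusion_id == fusion_id]

    def uniform_tube(self) -> Tube | None:
        """The single tube all fusion probes belong to, if unambiguous."""
        tubes = {p.tube for p in self.fusion_probes if p.tube is not None}
        if len(tubes) == 1:
            return tubes.pop()
        return None


def lineages_for(manifest: PanelManifest, fusion_id: str) -> frozenset[Lineage]:
    """Lineage labels associated with ``fusion_id``; empty for unknown ids.

    Returning an empty set (rather than raising) lets concordance checks
    degrade to "not assessable" for fusions without a lineage annotation.
    """
    return manifest.lineage_map.get(fusion_id, frozenset())


# -- serialization -------------------------------------------------------
#
# Manifest files are UTF-8 TSV with a required header row
#   probe_id  kind  fusion_id  tube  lineages
# ``lineages`` is a semicolon-separated list of lineage labels; empty
# cells mean "absent".  An optional leading comment line ``# name: X``
# carries the panel name.

_COLUMNS = ("probe_id", "kind", "fusion_id", "tube", "lineages")


def save_manifest(manifest: PanelManifest, path: str | Path) -> None:
    lines = [f"# name: {manifest.name}", "\t".join(_COLUMNS)]
    for p in manifest.probes:
        lineages = ";".join(sorted(l.value for l in p.lineages))
        lines.append(
            "\t".join(
                [
                    p.probe_id,
                    p.kind.value,
                    p.fusion_id or "",
                    p.tube.value if p.tube else "",
                    lineages,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_lineages(cell: str, probe_id: str) -> frozenset[Lineage]:
    labels = [tok.strip() for tok in cell.split(";") if tok.strip()]
    try:
        return frozenset(Lineage(tok) for tok in labels)
    except ValueError as exc:
        raise ManifestError(f"probe {probe_id!r}: unknown lineage in {cell!r}") from exc


def load_manifest(path: str | Path) -> PanelManifest:
    path = Path(path)
    name = path.stem
    probes: list[ProbeSet] = []
    header: list[str] | None = None
    with path.open(encoding="utf-8", newline="") as fh:
        for raw in csv.reader(fh, delimiter="\t"):
            if not raw or not any(cell.strip() for cell in raw):
                continue
            if raw[0].startswith("#"):
                text = raw[0].lstrip("#").strip()
                if text.lower().startswith("name:"):
                    name = text.split(":", 1)[1].strip()
                continue
            if header is None:
                header = [c.strip() for c in raw]
                if tuple(header) != _COLUMNS:
                    raise ManifestError(
                        f"manifest header must be {list(_COLUMNS)}, got {header}"
                    )
                continue
            row = dict(zip(_COLUMNS, (c.strip() for c in raw)))
            probe_id = row.get("probe_id", "")
            try:
                kind = ProbeKind(row.get("kind", ""))
            except ValueError as exc:
                raise ManifestError(
                    f"probe {probe_id!r}: unknown kind {row.get('kind')!r}"
                ) from exc
            tube_cell = row.get("tube", "")
            try:
                tube = Tube(tube_cell) if tube_cell else None
            except ValueError as exc:
                raise ManifestError(
                    f"probe {probe_id!r}: unknown tube {tube_cell!r}"
                ) from exc
            probes.append(
                ProbeSet(
                    probe_id=probe_id,
                    kind=kind,
                    fusion_id=row.get("fusion_id") or None,
                    tube=tube,
                    lineages=_parse_lineages(row.get("lineages", ""), probe_id),
                )
            )
    if header is None:
        raise ManifestError(f"{path}: empty manifest file (no header row)")
    return PanelManifest(name=name, probes=probes)
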