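"""Readers and writers for annotation artifacts, plus run configuration.

All artifacts are plain delimited text — the gold-standard pipeline this
emulates recorded nucleus coordinates and types to text files, and the
formats here keep that spirit:

* gold annotations: a TSV with one header line ``image_id width height``
  followed by one ``x  y  class`` line per nucleus (class codes P/N/O);
* judgments: a long-format TSV, one click per row, each row carrying the
  judgment metadata; a wide one-judgment-per-row dialect is also read
  and written on request;
* reports and configuration: JSON/YAML.

Parsing is strict and fail-fast with the offending line reported — a
quantification pipeline must never drop counts silently. Writers are
deterministic: stable ordering, coordinates as integers, percentages to
two decimals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .aggregate import AggregationConfig
from .consensus import ConsensusConfig, ConsensusNucleus
from .gates import GateConfig
from .model import (
    Canvas,
    Click,
    GoldAnnotation,
    Judgment,
    NucleusClass,
    Point,
    PositivityRecord,
)


class FormatError(ValueError):
    """Malformed artifact file; message names the file and line."""


_JUDGMENT_HEADER = (
    "image_id\tworker_id\tcountry\telapsed_seconds\tend_attempts\t"
    "afterthoughts\tx\ty\tlabel"
)
_WIDE_MAGIC = "#crowdihc-judgments-wide"


def _fmt_coord(v: float) -> str:
    return str(int(round(v)))


def _parse_int(token: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: {what} must be an integer, got {token!r}"
        ) from None


# ---------------------------------------------------------------------------
# gold annotations


def write_gold(annotation: GoldAnnotation, path: str | Path) -> None:
    """Write a gold annotation as TSV (header, then one nucleus per line)."""
    path = Path(path)
    lines = [f"{annotation.image_id}\t{annotation.canvas.width}\t"
             f"{annotation.canvas.height}"]
    for p, cls in annotation.nuclei:
        lines.append(f"{_fmt_coord(p.x)}\t{_fmt_coord(p.y)}\t{cls.value}")
    path.write_text("\n".join(lines) + "\n")


def read_gold(path: str | Path) -> GoldAnnotation:
    """Read a gold annotation TSV, validating every coordinate against
    the header canvas."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file; expected a header line")
    header = lines[0].split("\t")
    if len(header) != 3:
        raise FormatError(
            f"{path}:1: header must be 'image_id<TAB>width<TAB>height', "
            f"got {lines[0]!r}"
        )
    image_id = header[0]
    width = _parse_int(header[1], path, 1, "canvas width")
    height = _parse_int(header[2], path, 1, "canvas height")
    canvas = Canvas(width, height)
    nuclei: list[tuple[Point, NucleusClass]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got "
                f"{len(fields)}"
            )
        x = _parse_int(fields[0], path, lineno, "x coordinate")
        y = _parse_int(fields[1], path, lineno, "y coordinate")
        p = Point(float(x), float(y))
        if not canvas.contains(p):
            raise FormatError(
                f"{path}:{lineno}: point ({x}, {y}) outside canvas "
                f"{width}x{height}"
            )
        try:
            cls = NucleusClass.from_code(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        nuclei.append((p, cls))
    return GoldAnnotation(image_id=image_id, canvas=canvas, nuclei=nuclei)


# ---------------------------------------------------------------------------
# judgments


def _meta_fields(j: Judgment) -> list[str]:
    return [
        j.image_id,
        j.worker_id,
        j.country if j.country is not None else "NA",
        str(j.elapsed_seconds) if j.elapsed_seconds is not None else "NA",
        str(j.end_attempts),
        str(j.afterthoughts),
    ]


def write_judgments(
    judgments: list[Judgment], path: str | Path, dialect: str = "long"
) -> None:
    """Write judgments as TSV; the long one-click-per-row dialect is the
    default, the wide one-judgment-per-row dialect is available."""
    path = Path(path)
    if dialect == "long":
        lines = [_JUDGMENT_HEADER]
        for j in judgments:
            meta = _meta_fields(j)
            for c in j.clicks:
                lines.append("\t".join(
                    meta + [_fmt_coord(c.point.x), _fmt_coord(c.point.y),
                            c.label.value]
                ))
    elif dialect == "wide":
        lines = [_WIDE_MAGIC]
        for j in judgments:
            row = _meta_fields(j)
            for c in j.clicks:
                row += [_fmt_coord(c.point.x), _fmt_coord(c.point.y),
                        c.label.value]
            lines.append("\t".join(row))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta(fields: list[str], path: Path, lineno: int) -> dict:
    elapsed = fields[3]
    return {
        "image_id": fields[0],
        "worker_id": fields[1],
        "country": None if fields[2] == "NA" else fields[2],
        "elapsed_seconds": None if elapsed == "NA" else float(elapsed),
        "end_attempts": _parse_int(fields[4], path, lineno, "end_attempts"),
        "afterthoughts": _parse_int(fields[5], path, lineno, "afterthoughts"),
    }


def _parse_click(
    x: str, y: str, label: str, path: Path, lineno: int
) -> Click:
    if label not in ("P", "N"):
        raise FormatError(
            f"{path}:{lineno}: judgment click label must be P or N — the "
            f"task interface offers only positive/negative — got {label!r}"
        )
    return Click(
        Point(float(_parse_int(x, path, lineno, "x coordinate")),
              float(_parse_int(y, path, lineno, "y coordinate"))),
        NucleusClass.from_code(label),
    )


def read_judgments(path: str | Path) -> list[Judgment]:
    """Read a judgments TSV; both the long and wide dialects are
    accepted (auto-detected from the first line)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or (len(lines) == 1 and not lines[0].strip()):
        return []
    judgments: list[Judgment] = []
    if lines[0] == _WIDE_MAGIC:
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 6 or (len(fields) - 6) % 3 != 0:
                raise FormatError(
                    f"{path}:{lineno}: wide row must have 6 metadata fields "
                    f"plus (x, y, label) triplets, got {len(fields)} fields"
                )
            meta = _parse_meta(fields, path, lineno)
            clicks = [
                _parse_click(fields[i], fields[i + 1], fields[i + 2], path, lineno)
                for i in range(6, len(fields), 3)
            ]
            judgments.append(Judgment(clicks=clicks, **meta))
        return judgments
    if lines[0] != _JUDGMENT_HEADER:
        raise FormatError(
            f"{path}:1: unrecognised judgments file; expected the long-format "
            f"header or the wide-format marker line"
        )
    current_key: tuple[str, str] | None = None
    meta: dict = {}
    clicks: list[Click] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(
                f"{path}:{lineno}: expected 9 tab-separated fields, got "
                f"{len(fields)}"
            )
        key = (fields[0], fields[1])
        if key != current_key:
            if current_key is not None:
                judgments.append(Judgment(clicks=clicks, **meta))
            current_key = key
            meta = _parse_meta(fields, path, lineno)
            clicks = []
        clicks.append(_parse_click(fields[6], fields[7], fields[8], path, lineno))
    if current_key is not None:
        judgments.append(Judgment(clicks=clicks, **meta))
    return judgments


# ---------------------------------------------------------------------------
# consensus export (gold dialect, round-trippable)


def write_consensus(
    consensus: list[ConsensusNucleus],
    image_id: str,
    canvas: Canvas,
    path: str | Path,
) -> None:
    """Export consensus nuclei in the gold-annotation dialect: centroid
    rounded to integer pixels, class = majority label."""
    nuclei = []
    for n in consensus:
        x = min(max(round(n.centroid.x), 0), canvas.width - 1)
        y = min(max(round(n.centroid.y), 0), canvas.height - 1)
        nuclei.append((Point(float(x), float(y)), n.label))
    write_gold(GoldAnnotation(image_id=image_id, canvas=canvas, nuclei=nuclei),
               path)


# ---------------------------------------------------------------------------
# bundled reference positivity table (13 gold/crowd pairs)


def load_table1_fixture() -> list[tuple[str, float, float]]:
    """The bundled 13-image reference table of gold vs crowdsourced
    median positivity percentages: (image_id, gold %, crowd %)."""
    text = (resources.files("crowdihc") / "data" / "table1.tsv").read_text()
    rows: list[tuple[str, float, float]] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("image_id"):
            continue
        image_id, gold, crowd = line.split("\t")
        rows.append((image_id, float(gold), float(crowd)))
    if len(rows) != 13:
        raise FormatError(f"reference table must have 13 rows, found {len(rows)}")
    return rows


def fixture_records(rows: list[tuple[str, float, float]] | None = None
                    ) -> list[PositivityRecord]:
    """Wrap the reference table rows as positivity records (each crowd
    value standing in for its aggregate, with no per-judgment detail)."""
    rows = rows if rows is not None else load_table1_fixture()
    return [
        PositivityRecord(image_id=i, gold_positivity=g,
                         judgment_positivities=[c], crowd_positivity=c)
        for i, g, c in rows
    ]


# ---------------------------------------------------------------------------
# run configuration and reports


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run; fully serialisable,
    and echoed into every report for reproducibility."""

    gates: GateConfig = field(default_factory=GateConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    cutoff: float = 15.0
    seed: int = 0
    n_judgments_per_image: int = 10
    max_units_per_worker: int = 13

    def to_dict(self) -> dict:
        return {
            "gates": asdict(self.gates),
            "aggregation": asdict(self.aggregation),
            "consensus": asdict(self.consensus),
            "cutoff": self.cutoff,
            "seed": self.seed,
            "n_judgments_per_image": self.n_judgments_per_image,
            "max_units_per_worker": self.max_units_per_worker,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            gates=GateConfig(**d.get("gates", {})),
            aggregation=AggregationConfig(**d.get("aggregation", {})),
            consensus=ConsensusConfig(**d.get("consensus", {})),
            cutoff=d.get("cutoff", 15.0),
            seed=d.get("seed", 0),
            n_judgments_per_image=d.get("n_judgments_per_image", 10),
            max_units_per_worker=d.get("max_units_per_worker", 13),
        )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def write_report(report: dict, cfg: RunConfig, path: str | Path) -> None:
    """Write a run report as JSON with the effective config embedded."""
    payload = {"config": cfg.to_dict(), **report}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def write_scatter_csv(records: list[PositivityRecord], path: str | Path) -> None:
    """Flat CSV of per-image gold/crowd pairs (gold on X, crowd on Y),
    percentages to two decimals."""
    lines = ["image_id,gold_positivity,crowd_positivity"]
    for r in records:
        lines.append(f"{r.image_id},{r.gold_positivity:.2f},{r.crowd_positivity:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
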