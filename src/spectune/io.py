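"""Reading and writing landscapes, effect tables and trajectory reports.

Landscape TSV dialect: header ``genotype<TAB>lambda_max<TAB>functional``;
genotype is a "+"-joined list of mutation labels with the literal ``ancestor``
for the empty genotype; lambda_max is blank (or ``NF``) on nonfunctional rows.
The Unicode minus (U+2212) is normalised to ASCII "-" on read; output is
strict canonical form.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Dict, List, Optional, TextIO, Tuple, Union

import pandas as pd

from .landscape import (
    EffectTable,
    IMPUTED,
    Landscape,
    LandscapeError,
    MEASURED,
    PhenotypeRecord,
    SiteSet,
    bit_count,
    lattice_order,
)
from .trajectories import StepProfile, Trajectory

ANCESTOR_TOKEN = "ancestor"
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}
_NONFUNCTIONAL_TOKENS = {"", "nf", "na", "none"}


class ParseError(LandscapeError):
    """A landscape file violated the declared dialect."""


def _normalize(text: str) -> str:
    return text.replace("−", "-").strip()


def parse_landscape(source: Union[str, Path, TextIO]) -> Landscape:
    """Parse and validate a landscape TSV; errors carry line numbers."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = getattr(source, "name", "<stream>")
    else:
        name = str(source)
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{name}: empty file (missing ancestor)")

    header = [_normalize(h).lower() for h in lines[0].split("\t")]
    if header[:3] != ["genotype", "lambda_max", "functional"]:
        raise ParseError(
            f"{name}:1: expected header 'genotype\\tlambda_max\\tfunctional', "
            f"got {lines[0]!r}"
        )

    rows: List[Tuple[int, Tuple[str, ...], Optional[float], bool, str]] = []
    label_order: List[str] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = [_normalize(p) for p in raw.split("\t")]
        if len(parts) < 3:
            raise ParseError(f"{name}:{lineno}: expected 3 tab-separated fields")
        gtxt, ltxt, ftxt = parts[0], parts[1], parts[2]
        source_txt = parts[3] if len(parts) > 3 else MEASURED

        if gtxt.lower() == ANCESTOR_TOKEN:
            labels: Tuple[str, ...] = ()
        else:
            labels = tuple(p.strip() for p in gtxt.split("+"))
            if any(not lab for lab in labels):
                raise ParseError(f"{name}:{lineno}: bad genotype label in {gtxt!r}")
            for lab in labels:
                if lab not in label_order:
                    label_order.append(lab)

        flow = ftxt.lower()
        if flow in _TRUE:
            functional = True
        elif flow in _FALSE:
            functional = False
        else:
            raise ParseError(f"{name}:{lineno}: bad functional flag {ftxt!r}")

        if functional:
            try:
                lam: Optional[float] = float(ltxt)
            except ValueError:
                raise ParseError(
                    f"{name}:{lineno}: functional row needs a numeric "
                    f"lambda_max, got {ltxt!r}"
                ) from None
        else:
            if ltxt.lower() not in _NONFUNCTIONAL_TOKENS:
                try:
                    float(ltxt)
                except ValueError:
                    raise ParseError(
                        f"{name}:{lineno}: bad lambda_max {ltxt!r} on "
                        "nonfunctional row"
                    ) from None
                # a numeric λ on a nonfunctional row is only legal for
                # explicitly imputed records
                if source_txt != IMPUTED:
                    raise ParseError(
                        f"{name}:{lineno}: nonfunctional measured row must "
                        "leave lambda_max blank or 'NF'"
                    )
                lam = float(ltxt)
            else:
                lam = None
        rows.append((lineno, labels, lam, functional, source_txt))

    if not any(not labels for _, labels, *_ in rows):
        raise ParseError(f"{name}: missing ancestor row")

    sites = SiteSet(tuple(label_order))
    records: Dict[int, PhenotypeRecord] = {}
    first_line: Dict[int, int] = {}
    lambda_anc = None
    for lineno, labels, lam, functional, source_txt in rows:
        mask = sites.mask_of(labels)
        if mask in records:
            raise ParseError(
                f"{name}:{lineno}: duplicate genotype "
                f"{'+'.join(labels) or ANCESTOR_TOKEN!s} "
                f"(first seen at line {first_line[mask]})"
            )
        first_line[mask] = lineno
        if mask == 0:
            if not functional or lam is None:
                raise ParseError(f"{name}:{lineno}: ancestor must be functional "
                                 "with a lambda_max")
            lambda_anc = lam
        records[mask] = PhenotypeRecord(mask=mask, lambda_max=lam,
                                        functional=functional,
                                        source=source_txt)
    return Landscape(sites=sites, lambda_anc=lambda_anc, records=records)


def write_landscape(landscape: Landscape, path: Union[str, Path, TextIO],
                    round_to: Optional[float] = 0.1) -> None:
    """Write a landscape TSV in canonical (size, bitmask) row order.

    λ values are rounded to ``round_to`` nm on output (0.1 by default; pass
    None for full precision) — a formatting choice only, the in-memory
    landscape keeps full precision.
    """
    out_lines = ["genotype\tlambda_max\tfunctional\tsource"]
    for mask in lattice_order(landscape.sites.L):
        rec = landscape.records.get(mask)
        if rec is None:
            continue
        name = "+".join(landscape.sites.labels_of(mask)) or ANCESTOR_TOKEN
        if rec.lambda_max is None:
            lam = "NF"
        else:
            val = rec.lambda_max
            if round_to:
                val = round(val / round_to) * round_to
            lam = f"{val:.10g}"
        out_lines.append(f"{name}\t{lam}\t{str(rec.functional).lower()}\t{rec.source}")
    text = "\n".join(out_lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def effect_table_frame(effects: EffectTable) -> pd.DataFrame:
    """Effect report: subset, order, theta, se, p, imputed (one row per θ)."""
    rows = []
    for mask in effects.subsets():
        rows.append({
            "subset": "+".join(effects.sites.labels_of(mask)),
            "order": bit_count(mask),
            "theta": effects.theta[mask],
            "se": effects.se.get(mask) if effects.se else None,
            "p": effects.pvalue.get(mask) if effects.pvalue else None,
            "imputed": mask in effects.imputed,
        })
    return pd.DataFrame(rows)


def write_effect_table(effects: EffectTable, path: Union[str, Path]) -> None:
    effect_table_frame(effects).to_csv(path, sep="\t", index=False)


def trajectory_report_frame(paths) -> pd.DataFrame:
    """Trajectory report: one row per path with its profile summary."""
    rows = []
    for traj, prof in paths:
        rows.append({
            "ordering": ",".join(traj.order),
            "status": traj.status,
            "terminated_at": traj.terminated_at,
            "lambda_profile": ";".join(f"{x:.10g}" for x in prof.lambdas),
            "max_abs_delta": prof.max_abs_delta,
            "variance": prof.variance,
        })
    return pd.DataFrame(rows)


def write_trajectory_report(paths, path: Union[str, Path]) -> None:
    trajectory_report_frame(paths).to_csv(path, sep="\t", index=False)


def parse_ages_tsv(path: Union[str, Path]) -> Dict[str, float]:
    """Two-column (name, age-in-My) TSV → dict."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["name", "age"],
                        comment="#")
    return {str(r.name_): float(r.age) for r in
            frame.rename(columns={"name": "name_"}).itertuples(index=False)}


def write_json(obj, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
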