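"""Growth-phenotype predictions from pathway calls and concordance scoring.

Prediction: a strain is predicted to grow on a substrate iff the mapped
pathway is present; impaired and absent both predict no growth. Scoring:
weak growth counts as growth-positive, untested cells (nd) are excluded, and
a cell is concordant iff (plus and p/w) or (minus and n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sugarmap.pathways import PathwayMatrix, STATUS_PRESENT
from sugarmap.registry import PhenotypeMatrix, SUBSTRATES

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNTESTED = "untested"

#: Table-derived substrate -> pathway map for the printed phenotype panel.
DEFAULT_SUBSTRATE_MAP: dict[str, str] = {s: s for s in SUBSTRATES}

GROWTH_POSITIVE = frozenset({"p", "w"})


class PhenotypeError(ValueError):
    pass


def predict_growth(
    matrix: PathwayMatrix,
    substrate_map: dict[str, str],
    strains: list[str],
) -> dict[tuple[str, str], str]:
    """Predicted '+'/'-' per (strain, substrate)."""
    out: dict[tuple[str, str], str] = {}
    for strain in strains:
        for substrate, pathway_id in substrate_map.items():
            try:
                status = matrix.status(strain, pathway_id)
            except KeyError:
                raise PhenotypeError(
                    f"substrate {substrate} maps to uncalled pathway {pathway_id}"
                )
            out[(strain, substrate)] = "+" if status == STATUS_PRESENT else "-"
    return out


@dataclass
class ConcordanceReport:
    classes: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {CONCORDANT: 0, DISCORDANT: 0, UNTESTED: 0}
        for cls in self.classes.values():
            out[cls] += 1
        return out

    @property
    def discordant_cells(self) -> set[tuple[str, str]]:
        return {cell for cell, cls in self.classes.items() if cls == DISCORDANT}


def score_concordance(
    predicted: dict[tuple[str, str], str],
    observed: dict[tuple[str, str], str],
) -> ConcordanceReport:
    if set(predicted) != set(observed):
        raise PhenotypeError("predicted and observed matrices are not congruent")
    report = ConcordanceReport()
    for cell, pred in predicted.items():
        obs = observed[cell]
        if obs == "nd":
            report.classes[cell] = UNTESTED
        elif (pred == "+" and obs in GROWTH_POSITIVE) or (pred == "-" and obs == "n"):
            report.classes[cell] = CONCORDANT
        else:
            report.classes[cell] = DISCORDANT
    return report


def score_fixture(matrix: PhenotypeMatrix) -> ConcordanceReport:
    """Concordance of the packaged matrix's own predicted column (a
    transcription check, distinct from regenerated predictions)."""
    predicted = {k: c.predicted for k, c in matrix.cells.items()}
    observed = {k: c.observed for k, c in matrix.cells.items()}
    return score_concordance(predicted, observed)


def substrate_growth_counts(matrix: PhenotypeMatrix) -> dict[str, int]:
    """Per-substrate count of strains with observed growth (p or w)."""
    counts = {s: 0 for s in matrix.substrates}
    for (_, substrate), cell in matrix.cells.items():
        if cell.observed in GROWTH_POSITIVE:
            counts[substrate] += 1
    return counts


def write_report_tsv(report: ConcordanceReport, path) -> None:
    strains = sorted({s for s, _ in report.classes})
    substrates = sorted({x for _, x in report.classes})
    code = {CONCORDANT: "C", DISCORDANT: "D", UNTESTED: "."}
    with open(path, "w") as fh:
        fh.write("strain\t" + "\t".join(substrates) + "\n")
        for s in strains:
            fh.write(
                s + "\t" + "\t".join(code[report.classes[(s, x)]] for x in substrates) + "\n"
            )
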