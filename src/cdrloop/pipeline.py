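"""End-to-end remodelling: parse -> extract -> initialize -> predict ->
average -> graft -> (optional) relax, with a per-loop confidence report."""

from __future__ import annotations

from dataclasses import dataclass

from .confidence import ConfidenceReport, score_decoys
from .egnn import DecoySet, EGNNConfig, predict_loops
from .geometry import evaluate_cdr_rmsd
from .relaxation import RelaxationConfig, RelaxationResult, relax_loops
from .structures import (
    AntibodyModel,
    CDRDefinition,
    default_cdr_definitions,
    extract_loops,
    graft_loops,
)


@dataclass
class RemodelResult:
    grafted: AntibodyModel  # unrelaxed prediction, always retained
    decoys: DecoySet
    confidence: ConfidenceReport
    relaxed: RelaxationResult | None = None

    def report_dict(self, cutoff: float = 1.5) -> dict:
        return {
            "confidence_cutoff": cutoff,
            "loops": {
                lid: {
                    "inter_decoy_rmsd": score,
                    "passes_cutoff": bool(score <= cutoff),
                }
                for lid, score in sorted(self.confidence.loop_scores.items())
            },
            "member_seeds": list(self.decoys.member_seeds),
            "relaxation_backend": self.relaxed.backend if self.relaxed else None,
        }


def remodel(
    model: AntibodyModel,
    members: list[dict],
    egnn_cfg: EGNNConfig | None = None,
    definitions: list[CDRDefinition] | None = None,
    relax: bool = False,
    relax_cfg: RelaxationConfig | None = None,
    structure_id: str = "",
) -> RemodelResult:
    """Remodel all six CDR loops of a parsed antibody model."""
    egnn_cfg = egnn_cfg or EGNNConfig()
    defs = definitions or default_cdr_definitions()
    loops = extract_loops(model, defs, with_coords=False)
    decoys, predicted = predict_loops(loops, members, egnn_cfg)
    grafted = graft_loops(model, predicted, defs)
    result = RemodelResult(
        grafted=grafted,
        decoys=decoys,
        confidence=score_decoys(decoys, structure_id=structure_id),
    )
    if relax:
        result.relaxed = relax_loops(grafted, relax_cfg, defs)
    return result


def attach_reference_errors(
    result: RemodelResult,
    reference: AntibodyModel,
    definitions: list[CDRDefinition] | None = None,
) -> RemodelResult:
    """Fill the confidence report's per-loop errors from a reference structure."""
    errors = evaluate_cdr_rmsd(result.grafted, reference, definitions)
    result.confidence.loop_errors.update(errors)
    return result
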