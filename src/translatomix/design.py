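"""Experimental design: sample classes, targets (indicator) matrix,
contrasts, and the type x treatment model for translational efficiency.

A study has two conditions (control and experiment, with user-chosen
labels) and 1 + K fractions: the transcription fraction (total cytoplasmic
RNA) plus K polysome fractions.  Every sample is assigned to exactly one
condition x fraction class.  Classes are named ``<label>.transcription``
and ``<label>.translation.<k>``.

The one-way layout is encoded as a samples x classes indicator matrix (the
"targets" frame) and tested through K+1 experiment-minus-control contrast
columns, one for transcription and one per polysome fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MICROARRAY, RNASEQ, ValidationError

#: fraction index of the transcription (total RNA) fraction
TRANSCRIPTION = 0

MODERATED_LM = "moderated_lm"
NB_GLM = "nb_glm"

CONTROL = "control"
EXPERIMENT = "experiment"


class DesignError(ValidationError):
    """A sample design is internally inconsistent or incompatible with the data."""


@dataclass
class SampleDesign:
    """Assignment of samples to condition x fraction classes.

    ``assignment`` maps each sample id to ``(condition, fraction)`` where
    condition is ``"control"`` or ``"experiment"`` and fraction is 0 for
    transcription or 1..K for the polysome fractions.
    """

    platform: str
    engine: str
    control_label: str
    experiment_label: str
    n_fractions: int
    assignment: dict[str, tuple[str, int]] = field(default_factory=dict)

    def label(self, condition: str) -> str:
        if condition == CONTROL:
            return self.control_label
        if condition == EXPERIMENT:
            return self.experiment_label
        raise DesignError(f"unknown condition {condition!r}")

    def class_name(self, condition: str, fraction: int) -> str:
        lab = self.label(condition)
        if fraction == TRANSCRIPTION:
            return f"{lab}.transcription"
        return f"{lab}.translation.{fraction}"

    def class_names(self) -> list[str]:
        """All class names in canonical order: control before experiment,
        transcription before polysome fractions, fraction index ascending."""
        names = []
        for k in range(self.n_fractions + 1):
            for cond in (CONTROL, EXPERIMENT):
                names.append(self.class_name(cond, k))
        return names

    def samples_in_class(self, condition: str, fraction: int) -> list[str]:
        return [
            s
            for s, (c, f) in self.assignment.items()
            if c == condition and f == fraction
        ]


def _check_label(label: str) -> None:
    if not label:
        raise DesignError("condition labels must be non-empty")
    if label[0].isdigit():
        raise DesignError(
            f"label {label!r} begins with a number; labels cannot begin "
            "with a number"
        )


def validate_design(design: SampleDesign, matrix: ExpressionMatrix) -> SampleDesign:
    """Validate a design against a matrix; returns the design unchanged.

    Checks condition labels, the engine/platform pairing, that every matrix
    sample is assigned exactly once, that every class has at least one
    sample, and that at least one residual degree of freedom remains
    (samples minus classes >= 1) so variances are estimable.
    """
    _check_label(design.control_label)
    _check_label(design.experiment_label)
    if design.control_label == design.experiment_label:
        raise DesignError("control and experiment labels must be distinct")
    if design.platform not in (MICROARRAY, RNASEQ):
        raise DesignError(f"unknown platform {design.platform!r}")
    if design.engine not in (MODERATED_LM, NB_GLM):
        raise DesignError(f"unknown engine {design.engine!r}")
    if design.engine == NB_GLM and design.platform != RNASEQ:
        raise DesignError(
            "the negative-binomial GLM engine models counts and requires "
            "platform='rnaseq'"
        )
    if design.n_fractions < 1:
        raise DesignError("n_fractions must be >= 1")

    assigned = list(design.assignment)
    if len(assigned) != len(set(assigned)):
        raise DesignError("a sample is assigned more than once")
    matrix_samples = set(matrix.sample_ids)
    unassigned = matrix_samples - set(assigned)
    if unassigned:
        raise DesignError(f"matrix samples not assigned to any class: {sorted(unassigned)}")
    extra = set(assigned) - matrix_samples
    if extra:
        raise DesignError(f"assigned samples not present in the matrix: {sorted(extra)}")

    for sample, (cond, frac) in design.assignment.items():
        if cond not in (CONTROL, EXPERIMENT):
            raise DesignError(f"sample {sample!r} has unknown condition {cond!r}")
        if not (0 <= frac <= design.n_fractions):
            raise DesignError(
                f"sample {sample!r} has fraction {frac}, outside 0..{design.n_fractions}"
            )
    for k in range(design.n_fractions + 1):
        for cond in (CONTROL, EXPERIMENT):
            if not design.samples_in_class(cond, k):
                raise DesignError(
                    f"class {design.class_name(cond, k)} has no samples"
                )
    n_classes = 2 * (design.n_fractions + 1)
    if len(assigned) - n_classes < 1:
        raise DesignError(
            f"no residual degrees of freedom: {len(assigned)} samples for "
            f"{n_classes} classes; at least one class needs replication"
        )
    return design


def build_targets(
    design: SampleDesign, matrix: ExpressionMatrix
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Reorder the matrix by class and build the samples x classes
    indicator ("targets") matrix.

    Samples are grouped in the canonical class order (control transcription,
    experiment transcription, control fraction 1, experiment fraction 1,
    ...); within a class samples are ordered by identifier, so the output
    is fully determined by the design and the matrix contents, independent
    of the input column order.
    """
    order: list[str] = []
    for k in range(design.n_fractions + 1):
        for cond in (CONTROL, EXPERIMENT):
            members = sorted(
                s for s in matrix.sample_ids if design.assignment.get(s) == (cond, k)
            )
            order.extend(members)
    reordered = matrix.subset_samples(order)
    classes = design.class_names()
    targets = pd.DataFrame(0, index=order, columns=classes, dtype=int)
    for sample in order:
        cond, frac = design.assignment[sample]
        targets.loc[sample, design.class_name(cond, frac)] = 1
    return reordered, targets


def build_contrasts(design: SampleDesign) -> pd.DataFrame:
    """Build the classes x (K+1) contrasts matrix.

    Each column is experiment minus control for one fraction —
    transcription first, then polysome fractions in ascending order.  A
    column carries +1 on the experiment class, -1 on the matched control
    class and 0 elsewhere, so every column sums to zero.
    """
    classes = design.class_names()
    cols = {}
    for k in range(design.n_fractions + 1):
        exp_cls = design.class_name(EXPERIMENT, k)
        ctl_cls = design.class_name(CONTROL, k)
        col = pd.Series(0, index=classes, dtype=int)
        col[exp_cls] = 1
        col[ctl_cls] = -1
        cols[f"{exp_cls}-{ctl_cls}"] = col
    return pd.DataFrame(cols)


def build_te_design(design: SampleDesign, fraction: int) -> tuple[pd.DataFrame, int]:
    """Model matrix for the translational-efficiency interaction test.

    Uses the transcription samples plus the samples of polysome fraction
    ``fraction`` and encodes the model ``type + treatment + type:treatment``
    with type = 1 for polysome (0 for total RNA), treatment = 1 for
    experiment (0 for control) and an intercept for the reference
    control/total cell.  The interaction coefficient — the
    condition-dependent change in polysome loading over and above the
    transcription change — is the translational-efficiency effect.

    Returns the samples x 4 model matrix and the column index of the
    interaction term.
    """
    if not (1 <= fraction <= design.n_fractions):
        raise DesignError(
            f"fraction {fraction} outside 1..{design.n_fractions}"
        )
    rows = {}
    for cond in (CONTROL, EXPERIMENT):
        for frac, type_code in ((TRANSCRIPTION, 0), (fraction, 1)):
            members = design.samples_in_class(cond, frac)
            if not members:
                raise DesignError(
                    f"type x treatment cell ({'polysome' if type_code else 'total'}, "
                    f"{cond}) is empty for fraction {fraction}; the "
                    "interaction is unidentifiable"
                )
            treat = 1 if cond == EXPERIMENT else 0
            for s in members:
                rows[s] = (1, type_code, treat, type_code * treat)
    X = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["intercept", "type", "treatment", "type:treatment"],
    )
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < 4:
        raise DesignError("translational-efficiency model matrix is rank deficient")
    return X, 3


def design_from_dict(cfg: dict) -> SampleDesign:
    """Build a :class:`SampleDesign` from a plain config mapping.

    Expected keys: ``platform``, ``engine``, ``control_label``,
    ``experiment_label``, ``n_fractions`` and ``assignments`` — the latter a
    mapping sample id -> ``{condition, fraction}`` (fraction 0 or the word
    ``transcription`` for total RNA).
    """
    assignment = {}
    for sample, entry in cfg["assignments"].items():
        frac = entry["fraction"]
        if isinstance(frac, str):
            frac = 0 if frac == "transcription" else int(frac)
        assignment[str(sample)] = (entry["condition"], int(frac))
    return SampleDesign(
        platform=cfg["platform"],
        engine=cfg.get("engine", MODERATED_LM),
        control_label=cfg["control_label"],
        experiment_label=cfg["experiment_label"],
        n_fractions=int(cfg["n_fractions"]),
        assignment=assignment,
    )
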