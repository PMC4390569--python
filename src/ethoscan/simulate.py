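"""Synthetic courtship studies with known ground truth.

Generates complete study bundles - scan-sampled observation tables,
line-level copulation durations, inbred-panel genotypes and covariates -
from a fully specified generative model, so that every pipeline stage has a
parameter-recovery test. The default :class:`PanelSpec` emulates the study
design the pipeline targets: 166 inbred lines, 10-15 males per line assayed
in 5 blocks, 30 scans per male, a panel-average joint transition matrix
whose heaviest cells are E->E (sustained copulation) and A->A (no
engagement), a two-group noninitiator structure (most lines produce none;
a minority produce them at rate ~0.122), and one biallelic causal variant
shifting the copulation-to-no-engagement (E->A) transition.

Generative model
----------------
* Between-line variation enters on the CONDITIONAL rows of the transition
  matrix: each line's row is Dirichlet-distributed around the base row with
  a common concentration; smaller concentration means more between-line
  variance and higher realized heritability of the joint phenotypes. The
  analyzed phenotypes are joint probabilities, so the concentration ->
  realized-H2 map is calibrated numerically, not analytically.
* Block effects tilt each male's transition rows exponentially along the
  category order (a positive offset nudges behavior toward copulation),
  sized to produce block variance shares of a few percent.
* Each male is a length-T first-order chain started at A (flies begin
  separated by the divider); categories are mapped back to ordinal scores
  uniformly within each category's preimage, except that an advancing
  chain takes the higher ordinal of a two-score category, emulating the
  scoring rule that ties go to the behavior closest to copulation.
* Noninitiator males replace the chain with uniform scores in {1, 2}.
* Copulation durations are drawn per line with a configurable negative
  correlation to the line's true E->A rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import GenotypeMatrix
from .observations import CATEGORIES, CATEGORY_PREIMAGE, MaleSequence, ObservationTable

__all__ = [
    "DEFAULT_BASE_JOINT",
    "PanelSpec",
    "GroundTruth",
    "SimulatedPanel",
    "base_to_conditional",
    "simulate_line_matrices",
    "simulate_male",
    "simulate_panel",
    "simulate_traits",
]

# Panel-average joint transition probabilities used as the generator's
# base matrix (rows = state at t, cols = state at t+1, order A..E),
# renormalized to sum to 1. Dominated by E->E (sustained copulation) and
# A->A (sustained no-engagement).
_RAW_BASE = np.array([
    [0.23,   0.025,  0.023,  0.0049, 0.015],
    [0.019,  0.022,  0.014,  0.0034, 0.0093],
    [0.017,  0.012,  0.042,  0.087,  0.015],
    [0.0039, 0.0029, 0.0080, 0.0050, 0.0030],
    [0.017,  0.0023, 0.0043, 0.0020, 0.69],
])
DEFAULT_BASE_JOINT = _RAW_BASE / _RAW_BASE.sum()


def base_to_conditional(joint: np.ndarray,
                        fallback_self_loop: bool = True) -> np.ndarray:
    """Convert a joint transition matrix (sums to 1) to row-stochastic form.

    Rows with zero total get a self-loop when ``fallback_self_loop`` is
    set, else raise.
    """
    joint = np.asarray(joint, dtype=float)
    if (joint < 0).any():
        raise ValueError("joint matrix entries must be nonnegative")
    out = np.zeros_like(joint)
    for i, row in enumerate(joint):
        s = row.sum()
        if s > 0:
            out[i] = row / s
        elif fallback_self_loop:
            out[i, i] = 1.0
        else:
            raise ValueError(f"row {i} of joint matrix sums to zero")
    return out


@dataclass
class PanelSpec:
    """Study-design parameters for a synthetic panel.

    Defaults mirror the emulated design: 166 lines x 10-15 males x 30
    scans in 5 blocks; concentration 57 (calibrated once against the
    pipeline) puts realized broad-sense heritability of the E->E joint
    phenotype near 0.095 and block_sd 0.05 puts the block variance share
    of the MMP score at a few percent; 20% of lines produce
    noninitiators at within-line rate 0.122; the causal variant moves
    E->A conditional mass by ``causal_effect`` in carrier lines; line
    copulation durations correlate with true E->A at ``duration_corr``.
    """

    n_lines: int = 166
    males_per_line: tuple[int, int] = (10, 15)
    n_blocks: int = 5
    T: int = 30
    base_joint: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASE_JOINT.copy())
    concentration: float = 57.0
    block_sd: float = 0.05
    noninit_line_fraction: float = 0.2
    noninit_rate: float = 0.122
    n_variants: int = 1000
    causal_effect: float = 0.05
    duration_corr: float = -0.35
    duration_mean: float = 20.0
    duration_sd: float = 4.0
    duration_pair_sd: float = 3.0
    n_duration_lines: int = 35
    pairs_per_duration_line: tuple[int, int] = (10, 15)
    tie_rule: bool = True

    def validate(self) -> None:
        if abs(self.base_joint.sum() - 1.0) > 1e-9:
            raise ValueError("base joint matrix must sum to 1")
        if (self.base_joint < 0).any():
            raise ValueError("base joint matrix must be nonnegative")
        for r in (self.noninit_rate, self.noninit_line_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class GroundTruth:
    """Everything needed to score pipeline recovery on a simulated panel."""

    line_ids: list[str]
    line_conditional: np.ndarray          # (n_lines, 5, 5)
    line_noninit_rate: np.ndarray         # (n_lines,)
    block_offsets: dict[str, float]
    causal_variant: str | None
    causal_effect: float
    carrier_lines: list[str]
    line_ea_rate: np.ndarray              # conditional E->A per line
    duration_line_means: dict[str, float]
    spec: PanelSpec

    def to_json(self, path) -> None:
        d = {
            "line_ids": self.line_ids,
            "line_conditional": self.line_conditional.tolist(),
            "line_noninit_rate": self.line_noninit_rate.tolist(),
            "block_offsets": self.block_offsets,
            "causal_variant": self.causal_variant,
            "causal_effect": self.causal_effect,
            "carrier_lines": self.carrier_lines,
            "line_ea_rate": self.line_ea_rate.tolist(),
            "duration_line_means": self.duration_line_means,
            "spec": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in dataclasses.asdict(self.spec).items()
            },
            "note": "synthetic data from a generative model; parameters "
                    "are generator choices, not estimates",
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def simulate_line_matrices(spec: PanelSpec,
                           rng: np.random.Generator) -> np.ndarray:
    """Per-line conditional matrices: Dirichlet rows around the base rows.

    Row i of each line is Dirichlet(concentration * base_row_i); as
    concentration -> infinity all lines converge to the base matrix.
    """
    base_cond = base_to_conditional(spec.base_joint)
    out = np.empty((spec.n_lines, 5, 5))
    for i in range(5):
        alpha = spec.concentration * np.maximum(base_cond[i], 1e-6)
        out[:, i, :] = rng.dirichlet(alpha, size=spec.n_lines)
    return out


def _tilt(matrix: np.ndarray, offset: float) -> np.ndarray:
    """Exponentially tilt each row along the category order A..E."""
    w = np.exp(offset * np.arange(5))
    tilted = matrix * w[None, :]
    return tilted / tilted.sum(axis=1, keepdims=True)


def simulate_male(
    cond: np.ndarray,
    noninit_rate: float,
    block_offset: float,
    T: int,
    rng: np.random.Generator,
    tie_rule: bool = True,
) -> list[int]:
    """Draw one male's length-T ordinal sequence.

    With probability ``noninit_rate`` the male is a noninitiator and only
    ever scores 1 or 2. Otherwise a first-order category chain starts at A
    under the block-tilted conditional matrix, and each category is
    converted to an ordinal score uniformly within its preimage - except
    that, when the chain has just advanced to a higher category and
    ``tie_rule`` is on, the higher ordinal of a two-score category is
    taken (ties at scan time go to the behavior nearest copulation).
    """
    if rng.random() < noninit_rate:
        return list(rng.integers(1, 3, size=T))
    P = _tilt(cond, block_offset)
    cat_idx = [0]
    for _ in range(T - 1):
        cat_idx.append(int(rng.choice(5, p=P[cat_idx[-1]])))
    seq = []
    for t, ci in enumerate(cat_idx):
        pre = CATEGORY_PREIMAGE[CATEGORIES[ci]]
        advanced = t > 0 and ci > cat_idx[t - 1]
        if len(pre) == 1:
            seq.append(pre[0])
        elif tie_rule and advanced:
            seq.append(pre[-1])
        else:
            seq.append(int(rng.choice(pre)))
    return seq


def _simulate_genotypes(spec: PanelSpec, line_ids: list[str],
                        rng: np.random.Generator) -> GenotypeMatrix:
    freqs = rng.uniform(0.05, 0.5, size=spec.n_variants)
    dos = (rng.random((spec.n_variants, len(line_ids)))
           < freqs[:, None]).astype(float) * 2.0
    variants = pd.DataFrame({
        "id": [f"v{i:06d}" for i in range(spec.n_variants)],
        "chrom": ["3R"] * spec.n_variants,
        "pos": np.arange(1, spec.n_variants + 1) * 100,
        "ref": ["A"] * spec.n_variants,
        "alt": ["T"] * spec.n_variants,
    })
    return GenotypeMatrix(variants, dos, list(line_ids))


@dataclass
class SimulatedPanel:
    """A complete synthetic study bundle."""

    observations: ObservationTable
    genotypes: GenotypeMatrix | None
    covariates: pd.DataFrame
    durations: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        """Write the bundle in the pipeline's input formats."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.observations.write(out / "observations.tsv")
        if self.genotypes is not None:
            g = self.genotypes
            wide = pd.concat(
                [g.variants,
                 pd.DataFrame(g.dosages, columns=g.lines)], axis=1
            )
            wide.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        self.covariates.to_csv(out / "covariates.tsv", sep="\t")
        self.durations.to_csv(out / "durations.tsv", sep="\t", index=False)
        self.truth.to_json(out / "ground_truth.json")


def simulate_panel(spec: PanelSpec | None = None,
                   seed: int = 0) -> SimulatedPanel:
    """Generate a full study bundle, reproducible from ``seed``."""
    spec = spec or PanelSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    line_ids = [f"L{i + 1:03d}" for i in range(spec.n_lines)]

    cond = simulate_line_matrices(spec, rng)

    # two-group noninitiator structure
    n_thresh = int(round(spec.noninit_line_fraction * spec.n_lines))
    thresh_lines = rng.choice(spec.n_lines, size=n_thresh, replace=False)
    noninit = np.zeros(spec.n_lines)
    noninit[thresh_lines] = spec.noninit_rate

    # genotypes and the causal E->A shift
    genotypes = None
    causal_id, carriers = None, []
    if spec.n_variants > 0:
        genotypes = _simulate_genotypes(spec, line_ids, rng)
        ci = int(rng.integers(spec.n_variants))
        causal_id = genotypes.variants.loc[ci, "id"]
        carrier_mask = genotypes.dosages[ci] > 0
        carriers = [l for l, c in zip(line_ids, carrier_mask) if c]
        e = CATEGORIES.index("E")
        a = CATEGORIES.index("A")
        for li in np.flatnonzero(carrier_mask):
            shift = min(spec.causal_effect, cond[li, e, e] - 1e-3)
            cond[li, e, a] += shift
            cond[li, e, e] -= shift
            cond[li, e] /= cond[li, e].sum()

    line_ea = cond[:, CATEGORIES.index("E"), CATEGORIES.index("A")].copy()

    # blocks: lines assigned randomly; per-block tilt offsets
    block_ids = [f"B{b + 1}" for b in range(spec.n_blocks)]
    line_block = rng.integers(spec.n_blocks, size=spec.n_lines)
    offsets = rng.normal(0.0, spec.block_sd, size=spec.n_blocks)
    block_offsets = {b: float(o) for b, o in zip(block_ids, offsets)}

    # males
    males: list[MaleSequence] = []
    lo, hi = spec.males_per_line
    for li, line in enumerate(line_ids):
        n_males = int(rng.integers(lo, hi + 1))
        b = int(line_block[li])
        for mi in range(n_males):
            seq = simulate_male(
                cond[li], noninit[li], offsets[b], spec.T, rng,
                tie_rule=spec.tie_rule,
            )
            males.append(MaleSequence(
                line=line, block=block_ids[b],
                trial=f"T{mi // 8 + 1}", arena=f"a{mi % 8 + 1}",
                male=f"m{mi + 1:02d}", ordinal_seq=seq,
            ))
    obs = ObservationTable(males, T=spec.T)

    # inert line covariates (endosymbiont / inversion status stand-ins)
    covariates = pd.DataFrame(
        {
            "wolbachia": rng.integers(0, 2, size=spec.n_lines),
            "inversion": rng.integers(0, 2, size=spec.n_lines),
        },
        index=pd.Index(line_ids, name="line"),
    )

    # copulation durations for a line subset, negatively tied to E->A
    n_dur = min(spec.n_duration_lines, spec.n_lines)
    dur_lines = sorted(rng.choice(spec.n_lines, size=n_dur, replace=False))
    z = (line_ea[dur_lines] - line_ea[dur_lines].mean())
    sd = z.std()
    z = z / sd if sd > 0 else z
    r = spec.duration_corr
    noise = rng.normal(size=n_dur)
    line_means = (spec.duration_mean
                  + spec.duration_sd * (r * z + np.sqrt(1 - r**2) * noise))
    dur_rows = []
    dlo, dhi = spec.pairs_per_duration_line
    truth_dur = {}
    for li, mu in zip(dur_lines, line_means):
        truth_dur[line_ids[li]] = float(mu)
        n_pairs = int(rng.integers(dlo, dhi + 1))
        durs = np.maximum(
            rng.normal(mu, spec.duration_pair_sd, size=n_pairs), 0.1)
        for d in durs:
            dur_rows.append((line_ids[li], float(d)))
    durations = pd.DataFrame(dur_rows, columns=["line", "duration"])

    truth = GroundTruth(
        line_ids=line_ids,
        line_conditional=cond,
        line_noninit_rate=noninit,
        block_offsets=block_offsets,
        causal_variant=causal_id,
        causal_effect=spec.causal_effect,
        carrier_lines=carriers,
        line_ea_rate=line_ea,
        duration_line_means=truth_dur,
        spec=spec,
    )
    return SimulatedPanel(obs, genotypes, covariates, durations, truth)


def simulate_traits(
    n_lines: int,
    males_per_line: int,
    n_blocks: int,
    sigma2_line: float,
    sigma2_block: float,
    sigma2_error: float,
    n_traits: int,
    rng: np.random.Generator,
):
    """Vectorized Gaussian traits under the additive line + block model.

    Returns (values of shape (n_traits, N), line labels, block labels)
    for a balanced panel; used for estimator-calibration studies where
    the full behavioral chain is unnecessary.
    """
    N = n_lines * males_per_line
    line_lab = np.repeat(np.arange(n_lines), males_per_line)
    block_lab = np.resize(np.arange(n_blocks), N)
    line_eff = rng.normal(0, np.sqrt(sigma2_line), (n_traits, n_lines))
    block_eff = rng.normal(0, np.sqrt(sigma2_block), (n_traits, n_blocks))
    err = rng.normal(0, np.sqrt(sigma2_error), (n_traits, N))
    values = line_eff[:, line_lab] + block_eff[:, block_lab] + err
    return values, line_lab, block_lab
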