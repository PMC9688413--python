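"""Synthetic cohorts with the latent structure the subtyping analysis assumes.

The generator emulates a small-cell lung cancer (SCLC) bulk RNA-seq cohort
with six molecular subtypes — mesenchymal (SCLC-M, YAP/TAZ-driven EMT),
inflamed (SCLC-I), ASCL1-, POU2F3- and NEUROD1-driven (SCLC-A/-P/-N) and
hypoxic (SCLC-H) — each sample being a four-cell-type mixture (epithelial,
fibroblast, endothelial, immune) with subtype-dependent mixing fractions.
Tumor epithelial expression carries the subtype program, a continuous
neuroendocrine (NE) → non-NE axis shared with a mouse-like single-cell time
course, and per-sample program-activity jitter that induces regulator–target
co-expression. Counts are negative-binomial around the mixture expectation.
Survival times are exponential with subtype-specific hazards and independent
right-censoring, and IHC records (vimentin, CD8+ TIL field counts) are
coupled to subtype.

Ground-truth labels, fractions, NE positions, program gene sets and
noise-free expectations are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import ExpressionMatrix, GeneSetCollection, ValidationError

SUBTYPES = ["SCLC-M", "SCLC-I", "SCLC-A", "SCLC-P", "SCLC-N", "SCLC-H"]
CELL_TYPES = ["epithelial", "fibroblast", "endothelial", "immune"]

# Named regulators, one per subtype program (YAP/TAZ-like for mesenchymal, etc.)
REGULATORS = {
    "SCLC-M": "REG_YAP1",
    "SCLC-I": "REG_IRF1",
    "SCLC-A": "REG_ASCL1",
    "SCLC-P": "REG_POU2F3",
    "SCLC-N": "REG_NEUROD1",
    "SCLC-H": "REG_HIF1A",
}

# Subtype anchors on the latent NE→non-NE axis (0 = fully neuroendocrine,
# 1 = fully non-NE); samples scatter tightly around their subtype's anchor.
_NE_POSITION_ANCHOR = {
    "SCLC-M": 0.85,
    "SCLC-I": 0.50,
    "SCLC-A": 0.15,
    "SCLC-P": 0.70,
    "SCLC-N": 0.30,
    "SCLC-H": 0.50,
}

# Dirichlet parameters over (epithelial, fibroblast, endothelial, immune).
# Mesenchymal and inflamed share the fibroblast prior; inflamed carries the
# largest immune prior.
_DEFAULT_FRACTION_DIRICHLET = {
    "SCLC-M": (96.0, 36.0, 12.0, 9.0),
    "SCLC-I": (60.0, 36.0, 12.0, 45.0),
    "SCLC-A": (126.0, 12.0, 9.0, 6.0),
    "SCLC-P": (114.0, 15.0, 12.0, 9.0),
    "SCLC-N": (126.0, 12.0, 9.0, 6.0),
    "SCLC-H": (102.0, 24.0, 12.0, 15.0),
}

# Per-subtype exponential hazards (events per month); mesenchymal and hypoxic
# tumors run the worst outcome.
_DEFAULT_HAZARDS = {
    "SCLC-M": 1 / 5.0,
    "SCLC-I": 1 / 20.0,
    "SCLC-A": 1 / 16.0,
    "SCLC-P": 1 / 14.0,
    "SCLC-N": 1 / 16.0,
    "SCLC-H": 1 / 6.0,
}

_PROGRAM_SIZE = 40
_MARKERS_PER_TYPE = 25


@dataclass
class CohortConfig:
    """Study conditions for a bulk human-like cohort."""

    n_samples: int = 120
    n_genes: int = 1000
    n_subtypes: int = 6
    subtype_proportions: tuple = (0.06, 0.20, 0.28, 0.16, 0.23, 0.07)
    program_effect: float = 3.0          # log2 fold elevation of subtype program genes
    ne_effect: float = 1.5               # log2 amplitude of the NE→non-NE axis
    ne_jitter: float = 0.015             # within-subtype sd around the NE anchor
    epi_immune_effect: float = 1.0       # weak epithelial-intrinsic immune program (inflamed)
    activity_sd: float = 0.05            # per-sample program-activity jitter (log2)
    n_background_modules: int = 6        # subtype-independent co-expression modules
    module_size: int = 25
    module_sd: float = 0.2               # per-sample activity sd of background modules
    fraction_dirichlet: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTION_DIRICHLET))
    noise_dispersion: float = 40.0       # NB size parameter; inf → Poisson
    gene_noise_sd: float = 0.15          # per-gene/sample biological log2 noise
    mean_depth: float = 2e6              # mean library size (reads)
    depth_cv: float = 0.2                # lognormal spread of library sizes
    survival_hazards: dict = field(default_factory=lambda: dict(_DEFAULT_HAZARDS))
    censor_low: float = 12.0             # uniform censoring window, months
    censor_high: float = 60.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_subtypes <= 0:
            raise ValidationError("counts must be positive")
        if self.n_subtypes != len(SUBTYPES):
            raise ValidationError(f"generator models exactly {len(SUBTYPES)} subtypes")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.shape != (self.n_subtypes,) or np.any(props < 0) or abs(props.sum() - 1) > 1e-9:
            raise ValidationError("subtype_proportions must be a simplex vector over subtypes")
        for st, alpha in self.fraction_dirichlet.items():
            if np.any(np.asarray(alpha, dtype=float) <= 0):
                raise ValidationError(f"Dirichlet parameters for {st} must be strictly positive")
        min_genes = 6 * _PROGRAM_SIZE + 2 * _PROGRAM_SIZE + 4 * _MARKERS_PER_TYPE + len(REGULATORS)
        if self.n_genes < min_genes:
            raise ValidationError(f"n_genes must be >= {min_genes} to hold all planted programs")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort (for recovery tests)."""

    subtype_labels: list
    fractions: pd.DataFrame                    # samples × 4, rows on the simplex
    ne_position: np.ndarray                    # per-sample latent NE→non-NE position in [0,1]
    programs: GeneSetCollection                # EMT/immune/hypoxia/NE/non-NE/per-regulator targets
    regulators: dict                           # subtype → regulator gene id
    expected_bulk_tpm: pd.DataFrame            # noise-free bulk expectation (TPM scale)
    epithelial_linear: pd.DataFrame            # per-sample epithelial expectation (linear)
    stroma_linear: pd.DataFrame                # fibro/endo/immune expectations (constant per type)
    celltype_signature: pd.DataFrame           # genes × 4 marker-gene reference (linear scale)


def _build_gene_architecture(n_genes: int):
    """Assign gene ids to programs, markers, regulators and housekeeping."""
    programs: dict[str, list] = {}
    gene_ids: list[str] = []

    def block(prefix: str, size: int) -> list:
        ids = [f"{prefix}_{i:03d}" for i in range(size)]
        gene_ids.extend(ids)
        return ids

    programs["EMT"] = block("EMT", _PROGRAM_SIZE)
    programs["IMMUNE"] = block("IMM", _PROGRAM_SIZE)
    programs["ASCL1_TARGETS"] = block("ATG", _PROGRAM_SIZE)
    programs["POU2F3_TARGETS"] = block("PTG", _PROGRAM_SIZE)
    programs["NEUROD1_TARGETS"] = block("NTG", _PROGRAM_SIZE)
    programs["HYPOXIA"] = block("HYP", _PROGRAM_SIZE)
    programs["NE"] = block("NEU", _PROGRAM_SIZE)
    programs["NONNE"] = block("NNE", _PROGRAM_SIZE)
    markers = {ct: block(f"MK{ct[:3].upper()}", _MARKERS_PER_TYPE) for ct in CELL_TYPES}
    gene_ids.extend(REGULATORS.values())
    n_house = n_genes - len(gene_ids)
    block("HK", n_house)
    return gene_ids, programs, markers


_SUBTYPE_PROGRAM = {
    "SCLC-M": "EMT",
    "SCLC-I": "IMMUNE",
    "SCLC-A": "ASCL1_TARGETS",
    "SCLC-P": "POU2F3_TARGETS",
    "SCLC-N": "NEUROD1_TARGETS",
    "SCLC-H": "HYPOXIA",
}


def _gene_directions(gene_ids, programs) -> np.ndarray:
    """Per-gene NE-axis direction: -1 for NE program, +1 for non-NE/EMT, else 0."""
    direction = np.zeros(len(gene_ids))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in programs["NE"]:
        direction[idx[g]] = -1.0
    for g in list(programs["NONNE"]) + list(programs["EMT"]):
        direction[idx[g]] = +1.0
    return direction


def generate_cohort(config: CohortConfig):
    """Generate a bulk cohort.

    Returns ``(counts, gene_lengths, truth, clinical)`` where ``counts`` is an
    integer :class:`ExpressionMatrix`, ``gene_lengths`` a per-gene kb Series,
    ``truth`` the planted :class:`GroundTruth` and ``clinical`` a table with
    survival and IHC columns.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_labels, s_base, s_frac, s_act, s_counts, s_surv, s_ihc) = [
        np.random.default_rng(c) for c in ss.spawn(7)
    ]

    n, g = config.n_samples, config.n_genes
    gene_ids, programs, markers = _build_gene_architecture(g)
    gidx = {gene: i for i, gene in enumerate(gene_ids)}
    sample_ids = [f"S{i:03d}" for i in range(n)]

    # --- subtype labels and latent NE positions
    labels = [SUBTYPES[k] for k in s_labels.choice(
        config.n_subtypes, size=n, p=np.asarray(config.subtype_proportions))]
    ne_pos = np.clip(
        np.array([_NE_POSITION_ANCHOR[st] for st in labels])
        + s_labels.normal(0.0, config.ne_jitter, size=n),
        0.0, 1.0,
    )

    # --- per-gene baselines and cell-type profiles (log2 scale)
    base = s_base.normal(3.0, 1.2, size=g)
    profiles = {ct: base.copy() for ct in CELL_TYPES}
    for ct in CELL_TYPES:
        for mk_ct, ids in markers.items():
            rows = [gidx[x] for x in ids]
            profiles[ct][rows] += 3.5 if mk_ct == ct else -1.5
    # immune cells express the immune program strongly
    imm_rows = [gidx[x] for x in programs["IMMUNE"]]
    profiles["immune"][imm_rows] += config.program_effect + 1.0

    direction = _gene_directions(gene_ids, programs)
    prog_rows = {p: [gidx[x] for x in ids] for p, ids in programs.items()}
    reg_rows = {st: gidx[r] for st, r in REGULATORS.items()}

    # --- per-sample epithelial expectation (log2): subtype program + NE axis + jitter
    epi_log = np.tile(profiles["epithelial"][:, None], (1, n))
    for j, st in enumerate(labels):
        prog = _SUBTYPE_PROGRAM[st]
        act = config.program_effect + s_act.normal(0.0, config.activity_sd)
        epi_log[prog_rows[prog], j] += act
        epi_log[reg_rows[st], j] += act
        if st == "SCLC-I":
            epi_log[prog_rows["IMMUNE"], j] += (
                config.epi_immune_effect - config.program_effect + s_act.normal(0, 0.1)
            )  # net: weak epithelial-intrinsic immune program
    # NE→non-NE axis (continuous, shared with the mouse time course)
    epi_log += config.ne_effect * direction[:, None] * ne_pos[None, :]
    epi_log += config.ne_effect * np.where(direction < 0, 1.0, 0.0)[:, None] * (1 - ne_pos[None, :])
    # NE-linked regulators ride the axis like their targets
    for st, axis in (("SCLC-A", -1), ("SCLC-N", -1), ("SCLC-M", +1)):
        r = reg_rows[st]
        epi_log[r, :] += config.ne_effect * (ne_pos if axis > 0 else (1 - ne_pos))
    # Subtype-independent co-expression modules (pathway heterogeneity): many
    # weak correlated axes, so no single within-subtype split direction
    # dominates. Modules live in the housekeeping background.
    hk_rows = [i for i, gid in enumerate(gene_ids) if gid.startswith("HK")]
    module_rows = []
    if config.n_background_modules and hk_rows:
        pick = s_act.choice(
            len(hk_rows),
            size=min(config.n_background_modules * config.module_size, len(hk_rows)),
            replace=False,
        )
        for m in range(config.n_background_modules):
            rows = [hk_rows[j] for j in pick[m * config.module_size:(m + 1) * config.module_size]]
            if not rows:
                break
            module_rows.append(rows)
            activity = s_act.normal(0.0, config.module_sd, size=n)
            epi_log[np.ix_(rows, range(n))] += activity[None, :]
    epi_log += s_act.normal(0.0, config.gene_noise_sd, size=(g, n))  # biological noise

    # --- mixing fractions
    fracs = np.vstack([
        s_frac.dirichlet(np.asarray(config.fraction_dirichlet[st], dtype=float))
        for st in labels
    ])

    # --- expected bulk in linear space
    epi_lin = 2.0 ** epi_log
    stroma_lin = {ct: 2.0 ** profiles[ct] for ct in CELL_TYPES[1:]}
    bulk_lin = fracs[:, 0][None, :] * epi_lin
    for k, ct in enumerate(CELL_TYPES[1:], start=1):
        bulk_lin += fracs[:, k][None, :] * stroma_lin[ct][:, None]
    bulk_tpm = 1e6 * bulk_lin / bulk_lin.sum(axis=0, keepdims=True)

    # --- counts: NB around depth × molar-fraction × length
    lengths_kb = pd.Series(np.exp(s_base.normal(0.7, 0.4, size=g)), index=gene_ids)
    depth = config.mean_depth * np.exp(s_counts.normal(0.0, config.depth_cv, size=n))
    read_rate = bulk_tpm * lengths_kb.to_numpy()[:, None]
    mu = depth[None, :] * read_rate / read_rate.sum(axis=0, keepdims=True)
    if np.isinf(config.noise_dispersion):
        counts = s_counts.poisson(mu)
    else:
        size = float(config.noise_dispersion)
        counts = s_counts.negative_binomial(size, size / (size + mu))
    counts_em = ExpressionMatrix(counts.astype(float), gene_ids, sample_ids, "counts")

    # --- survival
    haz = np.array([config.survival_hazards[st] for st in labels])
    t_event = s_surv.exponential(1.0 / haz)
    t_cens = s_surv.uniform(config.censor_low, config.censor_high, size=n)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    # --- IHC records coupled to subtype
    ihc = generate_ihc_cohort(n, labels, seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    clinical = ihc.copy()
    clinical.insert(0, "sample_id", sample_ids)
    clinical.insert(1, "os_time", np.round(os_time, 4))
    clinical.insert(2, "os_event", os_event)

    # --- ground truth containers
    truth_sets = {
        "EMT": programs["EMT"],
        "IMMUNE": programs["IMMUNE"],
        "HYPOXIA": programs["HYPOXIA"],
        "NE": programs["NE"],
        "NONNE": programs["NONNE"],
    }
    for st, reg in REGULATORS.items():
        truth_sets[f"TARGETS_{reg}"] = programs[_SUBTYPE_PROGRAM[st]]
    sig_genes = [x for ids in markers.values() for x in ids]
    sig = pd.DataFrame(
        {ct: (2.0 ** profiles[ct])[[gidx[x] for x in sig_genes]] for ct in CELL_TYPES},
        index=sig_genes,
    )
    truth = GroundTruth(
        subtype_labels=labels,
        fractions=pd.DataFrame(fracs, index=sample_ids, columns=CELL_TYPES),
        ne_position=ne_pos,
        programs=GeneSetCollection({k: set(v) for k, v in truth_sets.items()}),
        regulators=dict(REGULATORS),
        expected_bulk_tpm=pd.DataFrame(bulk_tpm, index=gene_ids, columns=sample_ids),
        epithelial_linear=pd.DataFrame(epi_lin, index=gene_ids, columns=sample_ids),
        stroma_linear=pd.DataFrame(stroma_lin, index=gene_ids),
        celltype_signature=sig,
    )
    return counts_em, lengths_kb, truth, clinical


# ---------------------------------------------------------------- time course


@dataclass
class TimeCourseConfig:
    """Mouse-like NE→non-NE single-cell time course."""

    n_cells: int = 600
    timepoints: tuple = (4, 7, 11, 14, 17, 21)
    cells_per_timepoint: tuple | None = None
    depth: float = 5000.0                # mean UMI per cell
    gradient_sharpness: float = 2.0      # log2 amplitude of the transition
    time_jitter: float = 0.12            # sd of latent time around the day anchor
    seed: int = 11

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValidationError("n_cells must be positive")
        tp = list(self.timepoints)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if self.cells_per_timepoint is None:
            base, extra = divmod(self.n_cells, len(tp))
            self.cells_per_timepoint = tuple(
                base + (1 if i < extra else 0) for i in range(len(tp))
            )
        if sum(self.cells_per_timepoint) != self.n_cells:
            raise ValidationError("cells_per_timepoint must sum to n_cells")


@dataclass
class TimeCourse:
    umi: sp.csr_matrix          # genes × cells
    gene_ids: list
    cell_ids: list
    day: np.ndarray             # per-cell day label
    latent_time: np.ndarray     # per-cell latent position in [0,1]


def timecourse_mean_log2(shared_genes, programs: GeneSetCollection, t, sharpness, base=None):
    """Noise-free log2 expression of each shared gene at latent time(s) ``t``.

    Two cells at identical latent time have identical expectations. NE-program
    genes decrease, non-NE/EMT-program genes increase along ``t``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    direction = np.zeros(len(shared_genes))
    ne = programs["NE"] if "NE" in programs else set()
    up = set()
    for name in ("NONNE", "EMT"):
        if name in programs:
            up |= programs[name]
    for i, gid in enumerate(shared_genes):
        if gid in ne:
            direction[i] = -1.0
        elif gid in up:
            direction[i] = +1.0
    if base is None:
        base = np.full(len(shared_genes), 3.0)
    log2mu = base[:, None] + sharpness * np.where(
        direction[:, None] < 0, (1.0 - t[None, :]), 0.0
    ) * np.abs(direction[:, None])
    log2mu += sharpness * np.where(direction[:, None] > 0, t[None, :], 0.0)
    return log2mu


def generate_mouse_timecourse(config: TimeCourseConfig, shared_genes, programs: GeneSetCollection):
    """Generate a mouse-like UMI time course over ``shared_genes``.

    ``programs`` must provide the NE (and non-NE/EMT) program memberships of
    the paired cohort so that the transition runs over shared genes.
    """
    shared_genes = list(shared_genes)
    if not shared_genes:
        raise ValidationError("shared_genes must be non-empty")
    if "NE" not in programs:
        raise ValidationError("programs must include the NE gene set")
    ss = np.random.SeedSequence(config.seed)
    rng_t, rng_base, rng_counts = [np.random.default_rng(c) for c in ss.spawn(3)]

    tp = np.asarray(config.timepoints, dtype=float)
    anchors = (tp - tp[0]) / (tp[-1] - tp[0])
    day = np.repeat(tp, config.cells_per_timepoint)
    anchor = np.repeat(anchors, config.cells_per_timepoint)
    latent = np.clip(anchor + rng_t.normal(0.0, config.time_jitter, size=len(day)), 0.0, 1.0)

    base = rng_base.normal(3.0, 1.0, size=len(shared_genes))
    log2mu = timecourse_mean_log2(shared_genes, programs, latent, config.gradient_sharpness, base)
    lin = 2.0 ** log2mu
    probs = lin / lin.sum(axis=0, keepdims=True)
    depth = rng_counts.gamma(shape=10.0, scale=config.depth / 10.0, size=len(day))
    umi = rng_counts.poisson(depth[None, :] * probs)
    cell_ids = [f"C{i:05d}" for i in range(len(day))]
    return TimeCourse(
        umi=sp.csr_matrix(umi),
        gene_ids=shared_genes,
        cell_ids=cell_ids,
        day=day,
        latent_time=latent,
    )


# ---------------------------------------------------------------- IHC


_IHC_PARAMS = {
    # (P(vimentin+), proportion range, intensity choices, CD8 Poisson mean)
    "SCLC-M": (0.95, (30, 90), (2, 3), 5.0),
    "SCLC-I": (0.50, (10, 60), (1, 2), 30.0),
    "other": (0.08, (5, 30), (1,), 12.0),
}


def generate_ihc_cohort(n: int, subtype_labels, seed: int) -> pd.DataFrame:
    """IHC records (vimentin proportion/intensity, five CD8 field counts).

    Mesenchymal tumors are vimentin-positive with low CD8 infiltration;
    inflamed tumors carry high CD8 counts; the remaining subtypes are mostly
    vimentin-negative.
    """
    subtype_labels = list(subtype_labels)
    if n != len(subtype_labels):
        raise ValidationError(f"n={n} does not match {len(subtype_labels)} labels")
    unknown = set(subtype_labels) - set(SUBTYPES)
    if unknown:
        raise ValidationError(f"unknown subtype labels {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for st in subtype_labels:
        p_pos, prop_rng, intens, cd8_mu = _IHC_PARAMS.get(st, _IHC_PARAMS["other"])
        positive = rng.random() < p_pos
        if positive:
            prop = float(np.round(rng.uniform(*prop_rng)))
            intensity = int(rng.choice(intens))
        else:
            prop, intensity = 0.0, 0
        cd8 = rng.poisson(cd8_mu, size=5)
        rows.append(
            {
                "subtype": st,
                "vimentin_proportion": prop,
                "vimentin_intensity": intensity,
                **{f"cd8_f{i+1}": int(c) for i, c in enumerate(cd8)},
            }
        )
    return pd.DataFrame(rows)
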