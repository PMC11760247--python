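"""Seeded synthetic cohorts with planted cross-disorder structure.

The generator emulates the statistical skeleton the downstream analysis
assumes, at the edge level (no voxel time series):

* eight symptom severities (four externalizing: ASD, ADHD, CD, ODD; four
  internalizing: GAD, Depression, ED, SpecificPhobia) driven by two
  correlated domain latents, so within-domain symptom correlations exceed
  cross-domain ones;
* per-condition connectomes in which a small set of *planted* edges load on
  the domain-specific latent component — positively for externalizing edges,
  negatively for internalizing edges — general edges load on the shared
  latent, and every other edge is pure noise;
* site/sex confounding as additive offsets on functional connectivity (FC);
* multi-wave follow-up in which FC declines with age, with the per-subject
  decline rate of planted edges coupled to baseline domain symptoms;
* polygenic-score covariates that correlate with one domain only.

Ground truth (planted edge sets, signs, latents, per-subject slopes) is
exported so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme, generate_parcellation

EXTERNALIZING_SYMPTOMS: tuple[str, ...] = ("ASD", "ADHD", "CD", "ODD")
INTERNALIZING_SYMPTOMS: tuple[str, ...] = ("GAD", "Depression", "ED", "SpecificPhobia")
SYMPTOMS: tuple[str, ...] = EXTERNALIZING_SYMPTOMS + INTERNALIZING_SYMPTOMS

#: symptom name -> "externalizing" | "internalizing"
DOMAIN_OF: dict[str, str] = {
    **{s: "externalizing" for s in EXTERNALIZING_SYMPTOMS},
    **{s: "internalizing" for s in INTERNALIZING_SYMPTOMS},
}

DEFAULT_CONDITIONS: tuple[str, ...] = (
    "stop_success",
    "stop_failure",
    "reward_feedback",
    "reward_anticipation",
)

DEFAULT_WAVES: tuple[tuple[str, float], ...] = (
    ("wave1", 14.0),
    ("wave2", 19.0),
    ("wave3", 23.0),
)


@dataclass
class SimulationConfig:
    """Parameter container for :func:`generate_cohort`.

    Effect sizes are standardized: ``effect_size_ext`` is the target Pearson
    correlation between a planted externalizing edge's FC and its driving
    latent.  ``symptom_domain_corr`` gives the expected within-domain
    correlation between any two symptoms of that domain (one value per
    domain); ``cross_domain_corr`` is the correlation between the two domain
    latents, so cross-domain symptom correlations are
    ``sqrt(a_ext * a_int) * cross_domain_corr``.
    """

    n_subjects: int = 600
    n_nodes: int = 60
    n_networks: int = 8
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    waves: tuple[tuple[str, float], ...] = DEFAULT_WAVES
    planted_ext_edges: int = 40
    planted_int_edges: int = 40
    planted_general_edges: int = 40
    effect_size_ext: float = 0.4
    effect_size_int: float = 0.4
    symptom_domain_corr: tuple[float, float] = (0.37, 0.28)
    cross_domain_corr: float = 0.30
    fc_decline_rate: float = 0.01
    slope_symptom_coupling: tuple[float, float] = (-0.20, 0.12)
    slope_sd: float = 0.01
    noise_sd: float = 0.1
    fc_baseline: float = 0.3
    n_sites: int = 8
    site_sd: float = 0.05
    sex_effect: float = 0.02
    age_jitter_sd: float = 0.4
    prs_corr: float = 0.3
    wave_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.symptom_domain_corr):
            self.symptom_domain_corr = (
                float(self.symptom_domain_corr),
                float(self.symptom_domain_corr),
            )
        else:
            self.symptom_domain_corr = tuple(float(a) for a in self.symptom_domain_corr)
        if np.isscalar(self.slope_symptom_coupling):
            self.slope_symptom_coupling = (
                float(self.slope_symptom_coupling),
                -float(self.slope_symptom_coupling),
            )
        else:
            self.slope_symptom_coupling = tuple(
                float(c) for c in self.slope_symptom_coupling
            )
        self.conditions = tuple(self.conditions)
        self.waves = tuple((str(w), float(a)) for w, a in self.waves)
        self.validate()

    def validate(self) -> None:
        a_ext, a_int = self.symptom_domain_corr
        for name, val in [
            ("symptom_domain_corr (ext)", a_ext),
            ("symptom_domain_corr (int)", a_int),
            ("cross_domain_corr", self.cross_domain_corr),
            ("prs_corr", self.prs_corr),
        ]:
            if not -1.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {val}")
        for c in self.slope_symptom_coupling:
            if not -1.0 <= c <= 1.0:
                raise ValueError("slope_symptom_coupling must lie in [-1, 1]")
        # cross-domain symptom correlation must stay below within-domain
        cross_sym = np.sqrt(max(a_ext, 0.0) * max(a_int, 0.0)) * self.cross_domain_corr
        if not min(a_ext, a_int) > cross_sym:
            raise ValueError(
                "within-domain symptom correlation must exceed the "
                "cross-domain one"
            )
        if not 0.0 <= self.wave_dropout < 1.0:
            raise ValueError("wave_dropout must lie in [0, 1)")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        n_planted = (
            self.planted_ext_edges
            + self.planted_int_edges
            + self.planted_general_edges
        )
        if min(
            self.planted_ext_edges,
            self.planted_int_edges,
            self.planted_general_edges,
        ) < 0:
            raise ValueError("planted edge counts must be nonnegative")
        if n_planted > n_edges:
            raise ValueError(
                f"{n_planted} planted edges exceed the {n_edges} available"
            )
        for eff in (self.effect_size_ext, self.effect_size_int):
            if not 0.0 <= eff < 1.0:
                raise ValueError("effect sizes must lie in [0, 1)")
        if len(self.waves) < 1:
            raise ValueError("at least one wave is required")
        if self.n_subjects < 8:
            raise ValueError("n_subjects must be >= 8")

    @property
    def wave_labels(self) -> tuple[str, ...]:
        return tuple(w for w, _ in self.waves)


@dataclass
class GroundTruth:
    """Exported generating quantities for scoring recovery."""

    ext_edges: dict[str, np.ndarray]
    int_edges: dict[str, np.ndarray]
    general_edges: dict[str, np.ndarray]
    true_signs: dict[tuple[str, int], int]
    true_slopes: pd.DataFrame  # per-subject per-edge yearly slope, one col per factor
    latents: pd.DataFrame  # shared / ext_specific / int_specific / ext / int


@dataclass
class SyntheticStudy:
    """One generated cohort: connectomes, symptoms, covariates, truth."""

    config: SimulationConfig
    parcellation: ParcellationScheme
    subjects: pd.Index
    connectomes: dict[tuple[str, str], np.ndarray]
    symptoms: pd.DataFrame  # long: subject_id, wave, then the 8 symptom columns
    covariates: pd.DataFrame  # long: subject_id, wave, site, sex, age, prs_ext, prs_int
    wave_present: pd.DataFrame  # subjects x wave labels, boolean
    truth: GroundTruth | None = None

    def symptoms_at(self, wave: str) -> pd.DataFrame:
        """Symptom table at one wave, indexed by subject, ordered as generated."""
        sub = self.symptoms[self.symptoms["wave"] == wave]
        return sub.set_index("subject_id").loc[self._present(wave), list(SYMPTOMS)]

    def covariates_at(self, wave: str) -> pd.DataFrame:
        sub = self.covariates[self.covariates["wave"] == wave]
        cols = ["site", "sex", "age", "prs_ext", "prs_int"]
        return sub.set_index("subject_id").loc[self._present(wave), cols]

    def connectome_at(self, condition: str, wave: str) -> np.ndarray:
        """Subjects-present x edges FC matrix for one (condition, wave)."""
        mat = self.connectomes[(condition, wave)]
        mask = self.wave_present[wave].to_numpy()
        return mat[mask]

    def _present(self, wave: str) -> pd.Index:
        return self.subjects[self.wave_present[wave].to_numpy()]


def _beta_for_effect(effect: float, noise_sd: float) -> float:
    """Loading giving corr(FC, latent) = effect with N(0, noise_sd) noise."""
    if effect <= 0.0:
        return 0.0
    return noise_sd * effect / np.sqrt(1.0 - effect**2)


def generate_cohort(config: SimulationConfig) -> SyntheticStudy:
    """Generate one seeded synthetic cohort.

    All randomness flows from ``config.seed`` through a single
    ``numpy.random.default_rng`` stream, so identical configs give
    bit-identical studies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    parc = generate_parcellation(config.n_nodes, config.n_networks, config.seed)
    n_edges = parc.n_edges
    subjects = pd.Index([f"S{k + 1:05d}" for k in range(n)], name="subject_id")

    # --- covariates -------------------------------------------------------
    site = rng.integers(0, config.n_sites, n)
    site_offsets = rng.normal(0.0, config.site_sd, config.n_sites)
    sex = rng.integers(0, 2, n)
    wave_labels = config.wave_labels
    mean_ages = np.array([a for _, a in config.waves])
    age1 = mean_ages[0] + rng.normal(0.0, config.age_jitter_sd, n)
    ages = np.empty((n, len(wave_labels)))
    ages[:, 0] = age1
    for w in range(1, len(wave_labels)):
        ages[:, w] = age1 + (mean_ages[w] - mean_ages[0]) + rng.normal(0.0, 0.1, n)

    # --- latent symptom model --------------------------------------------
    rho = config.cross_domain_corr
    shared = rng.normal(size=n)
    u_ext = rng.normal(size=n)
    u_int = rng.normal(size=n)
    sr = np.sqrt(abs(rho))
    l_ext = sr * np.sign(rho) * shared + np.sqrt(1.0 - abs(rho)) * u_ext
    l_int = sr * shared + np.sqrt(1.0 - abs(rho)) * u_int
    a_ext, a_int = config.symptom_domain_corr

    sym_frames = []
    for w, wave in enumerate(wave_labels):
        block = {}
        for s in SYMPTOMS:
            a = a_ext if DOMAIN_OF[s] == "externalizing" else a_int
            latent = l_ext if DOMAIN_OF[s] == "externalizing" else l_int
            block[s] = np.sqrt(a) * latent + np.sqrt(1.0 - a) * rng.normal(size=n)
        df = pd.DataFrame(block)
        df.insert(0, "wave", wave)
        df.insert(0, "subject_id", subjects)
        sym_frames.append(df)
    symptoms = pd.concat(sym_frames, ignore_index=True)

    # polygenic scores: one domain-specific component each
    pc = config.prs_corr
    prs_ext = pc * u_ext + np.sqrt(1.0 - pc**2) * rng.normal(size=n)
    prs_int = pc * u_int + np.sqrt(1.0 - pc**2) * rng.normal(size=n)

    # --- planted edge sets ------------------------------------------------
    ext_edges: dict[str, np.ndarray] = {}
    int_edges: dict[str, np.ndarray] = {}
    gen_edges: dict[str, np.ndarray] = {}
    true_signs: dict[tuple[str, int], int] = {}
    for cond in config.conditions:
        perm = rng.permutation(n_edges)
        k1, k2, k3 = (
            config.planted_ext_edges,
            config.planted_int_edges,
            config.planted_general_edges,
        )
        ext_edges[cond] = np.sort(perm[:k1])
        int_edges[cond] = np.sort(perm[k1 : k1 + k2])
        gen_edges[cond] = np.sort(perm[k1 + k2 : k1 + k2 + k3])
        for e in ext_edges[cond]:
            true_signs[(cond, int(e))] = +1
        for e in int_edges[cond]:
            true_signs[(cond, int(e))] = -1

    # --- per-subject decline slopes (per edge, per year) ------------------
    c_ext, c_int = config.slope_symptom_coupling
    base_ext = symptoms.loc[symptoms["wave"] == wave_labels[0], list(
        EXTERNALIZING_SYMPTOMS
    )].to_numpy().mean(axis=1)
    base_int = symptoms.loc[symptoms["wave"] == wave_labels[0], list(
        INTERNALIZING_SYMPTOMS
    )].to_numpy().mean(axis=1)

    def _coupled(base: np.ndarray, coupling: float) -> np.ndarray:
        z = (base - base.mean()) / base.std()
        eta = rng.normal(size=n)
        mix = coupling * z + np.sqrt(1.0 - coupling**2) * eta
        return -config.fc_decline_rate + config.slope_sd * mix

    slope_ext = _coupled(base_ext, c_ext)
    slope_int = _coupled(base_int, c_int)
    true_slopes = pd.DataFrame(
        {"externalizing": slope_ext, "internalizing": slope_int}, index=subjects
    )

    # --- connectomes ------------------------------------------------------
    beta_ext = _beta_for_effect(config.effect_size_ext, config.noise_sd)
    beta_int = _beta_for_effect(config.effect_size_int, config.noise_sd)
    beta_gen = _beta_for_effect(
        0.5 * (config.effect_size_ext + config.effect_size_int), config.noise_sd
    )

    connectomes: dict[tuple[str, str], np.ndarray] = {}
    for cond in config.conditions:
        signal = np.full((n, n_edges), config.fc_baseline)
        signal += site_offsets[site][:, None]
        signal += config.sex_effect * sex[:, None]
        signal[:, ext_edges[cond]] += beta_ext * u_ext[:, None]
        signal[:, int_edges[cond]] -= beta_int * u_int[:, None]
        signal[:, gen_edges[cond]] += beta_gen * shared[:, None]

        slope_mat = np.full(n_edges, -config.fc_decline_rate)[None, :].repeat(n, 0)
        slope_mat[:, ext_edges[cond]] = slope_ext[:, None]
        slope_mat[:, int_edges[cond]] = slope_int[:, None]

        for w, wave in enumerate(wave_labels):
            dt = (ages[:, w] - ages[:, 0])[:, None]
            noise = rng.normal(0.0, config.noise_sd, (n, n_edges))
            connectomes[(cond, wave)] = signal + slope_mat * dt + noise

    # --- wave presence ----------------------------------------------------
    present = np.ones((n, len(wave_labels)), dtype=bool)
    for w in range(1, len(wave_labels)):
        present[:, w] = rng.random(n) >= config.wave_dropout
    wave_present = pd.DataFrame(present, index=subjects, columns=list(wave_labels))

    cov_frames = []
    for w, wave in enumerate(wave_labels):
        df = pd.DataFrame(
            {
                "subject_id": subjects,
                "wave": wave,
                "site": site,
                "sex": sex,
                "age": ages[:, w],
                "prs_ext": prs_ext,
                "prs_int": prs_int,
            }
        )
        cov_frames.append(df)
    covariates = pd.concat(cov_frames, ignore_index=True)

    latents = pd.DataFrame(
        {
            "shared": shared,
            "ext_specific": u_ext,
            "int_specific": u_int,
            "ext": l_ext,
            "int": l_int,
        },
        index=subjects,
    )
    truth = GroundTruth(
        ext_edges=ext_edges,
        int_edges=int_edges,
        general_edges=gen_edges,
        true_signs=true_signs,
        true_slopes=true_slopes,
        latents=latents,
    )
    return SyntheticStudy(
        config=config,
        parcellation=parc,
        subjects=subjects,
        connectomes=connectomes,
        symptoms=symptoms,
        covariates=covariates,
        wave_present=wave_present,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk interchange (plain TSV + JSON)
# ---------------------------------------------------------------------------

def _edge_ids(n_edges: int) -> list[str]:
    return [f"e{k + 1}" for k in range(n_edges)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_study(study: SyntheticStudy, directory: str | Path) -> dict:
    """Write a study as TSV files plus a JSON manifest; returns the manifest.

    Connectomes go to one TSV per (condition, wave) with a ``subject_id``
    column followed by edge columns ``e1..eM`` in canonical upper-triangular
    order; a sidecar ``edges.tsv`` maps edge id to its 1-based node pair.
    Subjects missing a wave are omitted from that wave's rows.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc

    parc = study.parcellation
    files: list[Path] = []

    parc_df = pd.DataFrame(
        {
            "node_id": np.arange(parc.n_nodes) + 1,
            "network_id": parc.network_of + 1,
            "network_name": [parc.network_names[k] for k in parc.network_of],
        }
    )
    p = directory / "parcellation.tsv"
    parc_df.to_csv(p, sep="\t", index=False)
    files.append(p)

    ii, jj = parc.edge_pairs()
    edges_df = pd.DataFrame(
        {"edge_id": _edge_ids(parc.n_edges), "node_i": ii + 1, "node_j": jj + 1}
    )
    p = directory / "edges.tsv"
    edges_df.to_csv(p, sep="\t", index=False)
    files.append(p)

    for (cond, wave), mat in study.connectomes.items():
        mask = study.wave_present[wave].to_numpy()
        df = pd.DataFrame(mat[mask], columns=_edge_ids(parc.n_edges))
        df.insert(0, "subject_id", study.subjects[mask])
        p = directory / f"connectome_{cond}_{wave}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        files.append(p)

    def _present_rows(df: pd.DataFrame) -> pd.DataFrame:
        mask = [
            bool(study.wave_present.at[s, w])
            for s, w in zip(df["subject_id"], df["wave"])
        ]
        return df.loc[mask]

    p = directory / "symptoms.tsv"
    _present_rows(study.symptoms).to_csv(p, sep="\t", index=False, float_format="%.17g")
    files.append(p)
    p = directory / "covariates.tsv"
    _present_rows(study.covariates).to_csv(p, sep="\t", index=False, float_format="%.17g")
    files.append(p)

    if study.truth is not None:
        t = study.truth
        p = directory / "truth_slopes.tsv"
        t.true_slopes.reset_index().to_csv(p, sep="\t", index=False, float_format="%.17g")
        files.append(p)
        p = directory / "truth_latents.tsv"
        t.latents.reset_index().to_csv(p, sep="\t", index=False, float_format="%.17g")
        files.append(p)
        truth_json = {
            "ext_edges": {c: (v + 1).tolist() for c, v in t.ext_edges.items()},
            "int_edges": {c: (v + 1).tolist() for c, v in t.int_edges.items()},
            "general_edges": {c: (v + 1).tolist() for c, v in t.general_edges.items()},
            "true_signs": {f"{c}:e{e + 1}": s for (c, e), s in t.true_signs.items()},
        }
        p = directory / "truth.json"
        p.write_text(json.dumps(truth_json, indent=1))
        files.append(p)

    manifest = {
        "format": "stratnet-study/1",
        "seed": study.config.seed,
        "config": _config_to_jsonable(study.config),
        "symptoms": list(SYMPTOMS),
        "symptom_domains": dict(DOMAIN_OF),
        "files": {f.name: _sha256(f) for f in files},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["conditions"] = list(config.conditions)
    d["waves"] = [[w, a] for w, a in config.waves]
    d["symptom_domain_corr"] = list(config.symptom_domain_corr)
    d["slope_symptom_coupling"] = list(config.slope_symptom_coupling)
    return d


def read_study(directory: str | Path) -> SyntheticStudy:
    """Read a study previously written by :func:`write_study`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg = dict(manifest["config"])
    cfg["conditions"] = tuple(cfg["conditions"])
    cfg["waves"] = tuple((w, a) for w, a in cfg["waves"])
    cfg["symptom_domain_corr"] = tuple(cfg["symptom_domain_corr"])
    cfg["slope_symptom_coupling"] = tuple(cfg["slope_symptom_coupling"])
    config = SimulationConfig(**cfg)

    parc_df = pd.read_csv(directory / "parcellation.tsv", sep="\t")
    parc = ParcellationScheme(
        n_nodes=len(parc_df),
        network_of=parc_df["network_id"].to_numpy() - 1,
        network_names=tuple(
            parc_df.drop_duplicates("network_id").sort_values("network_id")[
                "network_name"
            ]
        ),
    )

    symptoms = pd.read_csv(directory / "symptoms.tsv", sep="\t", float_precision="round_trip")
    covariates = pd.read_csv(directory / "covariates.tsv", sep="\t", float_precision="round_trip")
    wave_labels = config.wave_labels
    subjects = pd.Index(
        symptoms.loc[symptoms["wave"] == wave_labels[0], "subject_id"],
        name="subject_id",
    )
    present = pd.DataFrame(False, index=subjects, columns=list(wave_labels))
    for wave in wave_labels:
        seen = symptoms.loc[symptoms["wave"] == wave, "subject_id"]
        present.loc[present.index.intersection(seen), wave] = True

    n_edges = parc.n_edges
    connectomes: dict[tuple[str, str], np.ndarray] = {}
    for cond in config.conditions:
        for wave in wave_labels:
            df = pd.read_csv(
                directory / f"connectome_{cond}_{wave}.tsv",
                sep="\t",
                float_precision="round_trip",
            )
            full = np.full((len(subjects), n_edges), np.nan)
            pos = subjects.get_indexer(df["subject_id"])
            full[pos] = df[_edge_ids(n_edges)].to_numpy()
            connectomes[(cond, wave)] = full

    truth = None
    tj = directory / "truth.json"
    if tj.exists():
        td = json.loads(tj.read_text())
        slopes = pd.read_csv(
            directory / "truth_slopes.tsv", sep="\t", float_precision="round_trip"
        ).set_index("subject_id")
        latents = pd.read_csv(
            directory / "truth_latents.tsv", sep="\t", float_precision="round_trip"
        ).set_index("subject_id")
        truth = GroundTruth(
            ext_edges={c: np.array(v) - 1 for c, v in td["ext_edges"].items()},
            int_edges={c: np.array(v) - 1 for c, v in td["int_edges"].items()},
            general_edges={
                c: np.array(v) - 1 for c, v in td["general_edges"].items()
            },
            true_signs={
                (k.split(":e")[0], int(k.split(":e")[1]) - 1): s
                for k, s in td["true_signs"].items()
            },
            true_slopes=slopes,
            latents=latents,
        )

    return SyntheticStudy(
        config=config,
        parcellation=parc,
        subjects=subjects,
        connectomes=connectomes,
        symptoms=symptoms,
        covariates=covariates,
        wave_present=present,
        truth=truth,
    )
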