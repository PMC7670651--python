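"""Shared fixtures: textured phantoms, tiny cohorts, and one session-scoped
end-to-end pipeline run on the default synthetic cohort."""

from pathlib import Path

import numpy as np
import pytest
from scipy import ndimage

from popatlas import Volume


def make_textured_phantom(shape=(48, 48, 48), voxel_mm=1.0, seed=3,
                          mean=800.0, contrast=0.5) -> Volume:
    """Ellipsoidal phantom with multi-scale internal texture: enough image
    structure for registration to lock onto everywhere."""
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    tex += 2.0 * ndimage.gaussian_filter(rng.standard_normal(shape), 5.0)
    tex /= np.abs(tex).max()
    idx = np.indices(shape) - (np.asarray(shape)[:, None, None, None] - 1) / 2
    rho = np.sqrt(
        (idx[0] / (0.40 * shape[0])) ** 2
        + (idx[1] / (0.38 * shape[1])) ** 2
        + (idx[2] / (0.39 * shape[2])) ** 2
    )
    data = np.where(rho <= 1.0, mean * (1 + contrast * tex) + 200.0, 0.0)
    return Volume(data, aff)


@pytest.fixture(scope="session")
def phantom64() -> Volume:
    return make_textured_phantom((64, 64, 64), 1.0, seed=3)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three-subject 32^3 cohort with ground truth, for fast driver tests."""
    from popatlas.synthgen import PhantomSpec, make_cohort, make_base_anatomy

    spec = PhantomSpec(grid_shape=(32, 32, 32), n_subjects=3,
                       warp_amplitude_mm=3.0, seed=7)
    base, labels = make_base_anatomy(spec.grid_shape, spec.voxel_mm, seed=spec.seed)
    return spec, base, labels, make_cohort(spec)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory) -> dict:
    """One full pipeline pass over the default desk-scale cohort (48^3,
    8 subjects, 4 mm warps, seed 1234): simulate -> build-template ->
    make-atlas -> validate, via the CLI.  Several acceptance checks read
    from this single run."""
    from popatlas.cli import run

    root = tmp_path_factory.mktemp("pipeline")
    cohort = root / "cohort"
    tmpl = root / "template"
    atlas = root / "atlas"
    val = root / "validate"
    rc = {}
    rc["simulate"] = run(["simulate", "--out", str(cohort), "--seed", "1234"])
    rc["build"] = run([
        "build-template", "--cohort", str(cohort / "manifest.tsv"),
        "--reference", str(cohort / "reference.nii.gz"),
        "--out", str(tmpl), "--seed", "1234",
    ])
    rc["atlas"] = run(["make-atlas", "--template-dir", str(tmpl),
                       "--cohort", str(cohort / "manifest.tsv"), "--out", str(atlas)])
    rc["validate"] = run(["validate", "--template-dir", str(tmpl),
                          "--atlas-dir", str(atlas),
                          "--cohort", str(cohort / "manifest.tsv"), "--out", str(val)])
    return {"rc": rc, "cohort": cohort, "template": tmpl, "atlas": atlas,
            "validate": val}
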