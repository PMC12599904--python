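import numpy as np
import pytest

from deeptdm.cohort import CohortConfig, simulate_cohort
from deeptdm.model import GointMLPConfig
from deeptdm.pk import DoseEvent, PatientCourse, TdmMeasurement, build_feature_sequence
from deeptdm.preprocessing import ScalerState, assemble_batches
from deeptdm.training import TrainConfig


#: Small architecture used throughout the suite: same topology as the
#: full model, scaled to desk size so tests train in seconds.
SMALL_MODEL = GointMLPConfig(
    gru_layers=2, hidden=8, n_mlps=4, mlp_layers=2, mlp_units=16, seed=0
)

SMALL_TRAIN = TrainConfig(
    max_epochs=120,
    batch_size=64,
    learning_rate=5e-3,
    warmup_epochs=30,
    early_stop_patience=30,
    seed=0,
)


def make_course(
    n_doses=3,
    dose_mg=1000.0,
    interval=12.0,
    scr=(0.9,),
    tdm=(),
    patient_id="T0001",
    **kw,
) -> PatientCourse:
    """Hand-built course: doses every ``interval`` h, optional TDM draws.

    ``tdm`` holds (dose_index, trough) pairs: the draw lands 0.5 h before
    dose ``dose_index + 1`` (or 0.5 h before the would-be next dose for the
    final event), attaching to dose ``dose_index``.
    """
    doses = [
        DoseEvent(
            time=i * interval,
            dose_mg=dose_mg if not isinstance(dose_mg, (list, tuple)) else dose_mg[i],
            admin_time=1.0,
            interval_h=interval if i > 0 else 0.0,
            loading=0,
        )
        for i in range(n_doses)
    ]
    measurements = [
        TdmMeasurement(
            time=(i + 1) * interval - 0.5,
            trough_ug_ml=v,
            time_since_dose_h=interval - 0.5,
        )
        for i, v in tdm
    ]
    defaults = dict(
        patient_id=patient_id,
        sex="male",
        age=60.0,
        height=170.0,
        weight=70.0,
        dialysis=0,
        creatinine_series=[(float(24 * j), s) for j, s in enumerate(scr)],
        dose_events=doses,
        tdm_measurements=sorted(measurements, key=lambda m: m.time),
    )
    defaults.update(kw)
    return PatientCourse(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    courses, truths = simulate_cohort(CohortConfig(n_patients=120, seed=11))
    return courses, truths


@pytest.fixture(scope="session")
def fitted_scaler(small_cohort):
    courses, _ = small_cohort
    feats = np.vstack([build_feature_sequence(c) for c in courses])
    return ScalerState.fit(feats)


@pytest.fixture(scope="session")
def small_batch(small_cohort, fitted_scaler):
    courses, _ = small_cohort
    return assemble_batches(courses, fitted_scaler)
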