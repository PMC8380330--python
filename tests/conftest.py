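"""Shared fixtures: small record builders used across the suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from cvratio.model import Sex, SexGroupSummary, StrainClass, StrainDataSet
from cvratio.model import AnimalMeasurement
from cvratio.stats import cv_ratio

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def make_group():
    """Factory for a SexGroupSummary with CV derived from sd/mean."""

    def _make(
        sex,
        n=10,
        mean=100.0,
        sd=None,
        cv=None,
        project_id="P1",
        parameter_key="glucose",
        strain="C57BL/6J",
    ):
        sex = Sex(sex)
        if sd is None:
            sd = (cv if cv is not None else 0.2) * mean
        return SexGroupSummary(
            project_id=project_id,
            parameter_key=parameter_key,
            strain=strain,
            sex=sex,
            n=n,
            mean=mean,
            sd=sd,
            cv=sd / mean,
        )

    return _make


@pytest.fixture
def make_dataset(make_group):
    """Factory for a StrainDataSet with chosen per-sex CVs (or a chosen
    CV ratio r via cv_f = r, cv_m = 1 - r)."""

    def _make(
        cv_f=None,
        cv_m=None,
        ratio=None,
        n_f=10,
        n_m=10,
        project_id="P1",
        parameter_key="glucose",
        strain="C57BL/6J",
    ):
        if ratio is not None:
            cv_f, cv_m = ratio, 1.0 - ratio
        female = make_group(
            "f", n=n_f, cv=cv_f, project_id=project_id,
            parameter_key=parameter_key, strain=strain,
        )
        male = make_group(
            "m", n=n_m, cv=cv_m, project_id=project_id,
            parameter_key=parameter_key, strain=strain,
        )
        return StrainDataSet(
            project_id=project_id,
            parameter_key=parameter_key,
            strain=strain,
            female=female,
            male=male,
            cv_ratio=cv_ratio(female.cv, male.cv),
        )

    return _make


@pytest.fixture
def make_animal():
    """Factory for an AnimalMeasurement with sensible defaults."""

    def _make(
        value=100.0,
        sex="f",
        age_weeks=12.0,
        treated=False,
        strain_class=StrainClass.INBRED,
        project_id="P1",
        parameter_key="glucose",
        strain="C57BL/6J",
    ):
        return AnimalMeasurement(
            project_id=project_id,
            parameter_key=parameter_key,
            strain=strain,
            strain_class=strain_class,
            sex=Sex(sex),
            age_weeks=age_weeks,
            treated=treated,
            value=value,
        )

    return _make
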