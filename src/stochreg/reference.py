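"""Reference cross-validation fixtures for the ten-instrument Bio-FET study.

``ASPECT_RATIOS`` lists the ten solution-well aspect ratios (well height
over gate diameter) of the published streptavidin/biotin Bio-FET
cross-validation ensemble, drawn uniformly between 0.1250 and 5.

``REFERENCE_K_STAR`` holds, for every (kernel side, error measure) pairing,
the published optimal bandwidth multipliers k* selected for those ten
instruments.  These columns are inputs to the leave-one-out consistency
arithmetic and let that stage be validated exactly without regenerating the
(undeposited) measurement ensemble.
"""

ASPECT_RATIOS = (
    4.0968,
    4.5407,
    0.74406,
    4.5777,
    3.2078,
    0.60051,
    1.4827,
    2.7910,
    4.7928,
    4.8288,
)

#: Default bounds of the aspect-ratio range sampled in the reference study.
EPSILON_MIN = 0.1250
EPSILON_MAX = 5.0

REFERENCE_K_STAR = {
    ("centered", "rmse"): (4, 4, 4, 4, 4, 4, 6, 6, 4, 5),
    ("centered", "mae"): (3, 4, 4, 4, 4, 4, 4, 3, 4, 6),
    ("centered", "std"): (4, 5, 4, 7, 5, 5, 6, 6, 4, 5),
    ("left", "rmse"): (10, 8, 8, 9, 10, 15, 10, 7, 9, 7),
    ("left", "mae"): (10, 8, 8, 9, 10, 15, 8, 7, 9, 7),
    ("left", "std"): (10, 8, 8, 9, 10, 15, 10, 7, 9, 7),
    ("right", "rmse"): (7, 7, 7, 7, 6, 7, 6, 6, 5, 6),
    ("right", "mae"): (6, 7, 8, 7, 6, 7, 6, 5, 5, 6),
    ("right", "std"): (7, 7, 7, 7, 6, 7, 6, 6, 5, 6),
}
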