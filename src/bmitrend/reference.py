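"""Published optimal model coefficient sets for adult BMI in England.

These are the reported optimal two-step models of the log-BMI position (mu)
and shape (sigma) fitted to Health Survey for England cohort data
(1991-2014 fitting window, year centred at 2003, sex coded 1=male/0=female).
They serve two roles here: as generating truth for the synthetic survey
generator, and as fixed inputs when projecting the England scenarios
without access to the original microdata.

The linear family is polynomial in the centred year; the non-linear family
replaces the year polynomial with the flattening trend a - b*exp(-c*year_c).
"""

# best-case family: polynomial in year, can peak and decline when extrapolated
LINEAR_MU = {
    "intercept": 2.972979986,
    "sex": 0.014412279,
    "age": 0.011426627,
    "year": 0.002521202,
    "age2": -9.53e-05,
    "year2": -1.21e-04,
}

LINEAR_SIGMA = {
    "intercept": -3.806540736,
    "sex": -0.023975995,
    "age": -3.82e-04,
    "year": 0.002788139,
    "age2": -2.76e-06,
    "year2": -4.12e-05,
    "sex:age": -9.37e-04,
    "sex:age2": 1.00e-05,
    "age:year": -3.50e-05,
    "age:year2": 1.42e-06,
    "mu": 2.452629849,
    "mu2": -0.373191887,
}

# worst-case family: exponential year trend flattening toward an asymptote
NONLINEAR_MU = {
    "a": 3.005399647,
    "b": 0.024797114,
    "c": 0.090789991,
    "sex": -0.002427327,
    "age": 0.011050057,
    "age2": -9.18e-05,
    "sex:age": 7.87e-04,
    "sex:age2": -7.45e-06,
}

NONLINEAR_SIGMA = {
    "a": 0.176626723,
    "b": -0.018412549,
    "c": -0.048293744,
    "sex": -0.023323632,
    "age": 5.21e-05,
    "age2": -5.67e-06,
    "sex:age": -9.73e-04,
    "sex:age2": 1.04e-05,
    "mu": 0.004283798,
}
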