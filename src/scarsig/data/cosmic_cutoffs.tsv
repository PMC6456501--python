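signature	cutoff
AC1	0
AC2	0.0104594
AC3	0.0819406
AC4	0.0175397
AC5	0
AC6	0.0015485
AC7	0.040133
AC8	0.242755
AC9	0.1151714
AC10	0.0100838
AC11	0.0992488
AC12	0.2106201
AC13	0.0078766
AC14	0.1443059
AC15	0.0379603
AC16	0.3674349
AC17	0.002648
AC18	0.3325386
AC19	0.1156454
AC20	0.1235028
AC21	0.1640255
AC22	0.0310222
AC23	0.0333866
AC24	0.0324018
AC25	0.0161191
AC26	0.0933522
AC27	0.0093201
AC28	0.0561643
AC29	0.0593621
AC30	0.0591536
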