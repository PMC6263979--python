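# Molar extinction coefficients of human hemoglobin, cm^-1 / (mol/L).
# Columns: wavelength_nm  eps_HbO2  eps_Hb
# Representative values compiled from standard tabulations of oxy- and
# deoxyhemoglobin absorption in the NIR window; adequate for simulation
# and unmixing round-trips (the isosbestic point sits near 800 nm).
600   3200   14677
625   1506    9443
650    368    3750
675    280    2796
700    290    1794
725    367    1244
750    518    1405
760    586    1548
775    700    1361
800    816     762
825    940     700
850   1058     691
875   1128     726
900   1198     761
925   1205     780
950   1204     693
975   1196     610
1000  1190     504
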