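code,e_oniom2,d_b3lyp,d_mp2,d_op
0-1,-4331.56,-33.41,-1.77,3.39
0-2,-4448.27,22.14,12.40,3.32
0-3,-4523.29,-6.92,-19.01,3.41
2-0,-4448.28,15.54,-9.27,3.47
3-0,-4523.29,9.21,-2.66,3.76
2-3,-4681.05,-10.76,-31.65,2.90
2-4,-4658.01,2.55,-14.25,3.39
2-5,-4676.14,23.00,5.71,3.28
2-6,-4523.56,21.98,10.76,3.30
3-1,-4562.62,-32.77,-43.43,3.54
3-2,-4679.34,15.17,-19.38,3.07
3-4,-4733.04,-5.67,-24.61,2.90
3-5,-4751.17,-11.79,-28.89,3.22
3-6,-4600.48,4.33,-6.89,3.31
3-9,-4637.82,2.26,-15.87,2.95
5-2,-4676.15,25.09,11.93,3.14
5-3,-4752.88,-0.74,-19.16,3.23
9-1,-4446.09,-26.59,2.55,3.30
2-PAM,-4292.53,0,0,4.42
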