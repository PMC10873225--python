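# electrostatic-repulsion 30-direction diffusion gradient scheme (unit xyz rows)
-0.43209691 0.90161866 0.01939223
-0.97141903 -0.22957352 0.06034122
0.75224239 0.64478630 0.13558029
-0.41003489 -0.90129036 0.13981082
-0.95949599 0.23585700 0.15407437
0.79832754 -0.57031975 0.19341283
-0.01706945 0.97996399 0.19844199
-0.72671214 0.63485030 0.26240154
0.03568089 -0.95482782 0.29500968
-0.74547233 -0.58517034 0.31913425
0.38850225 0.85946579 0.33224172
0.93042121 -0.15364371 0.33273110
0.87206425 0.28093037 0.40072692
0.45556840 -0.77968550 0.42959045
-0.86392106 -0.07798119 0.49755336
-0.35039016 0.78674947 0.50818502
-0.29303387 -0.76136064 0.57832615
-0.69401852 0.37055935 0.61727147
0.55963951 0.54191102 0.62700564
0.64462012 -0.40410713 0.64897020
0.08980462 0.73011370 0.67739878
-0.58947921 -0.41017374 0.69589637
0.16234048 -0.65458128 0.73835555
0.65098323 0.05846994 0.75683690
-0.26539559 0.46331894 0.84551803
-0.51662836 0.02122506 0.85594663
-0.17340359 -0.38964187 0.90449456
0.26506160 0.32857766 0.90652031
0.30569324 -0.22034570 0.92628258
-0.07353824 0.05620480 0.99570736
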